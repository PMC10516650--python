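import numpy as np
import pytest

from ribometrics.model_io import AtomicModel, AtomRecord
from ribometrics.synthetic import ToySpec, make_two_domain_pair


@pytest.fixture(scope="session")
def toy_pair():
    """Default-conditions two-domain pair (18° head swivel, no noise)."""
    return make_two_domain_pair(ToySpec(atoms_per_domain=30))


@pytest.fixture()
def random_cluster():
    """30 heavy atoms of mixed elements in a ~8 Å ball, seeded."""
    rng = np.random.default_rng(42)
    elements = ["C", "N", "O", "S", "P"]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=f"X{i}",
            element=elements[i % len(elements)],
            residue_name="LEU" if i % 3 == 0 else "ALA",
            chain_id="A",
            residue_number=i + 1,
            position=rng.normal(0.0, 3.0, 3),
        )
        for i in range(30)
    ]
    return AtomicModel(atoms, identifier="cluster")


def make_protein_cluster(positions, residue_name="LEU", element="C",
                         chain_id="A"):
    """Protein-like cluster with one atom per residue at given positions."""
    atoms = [
        AtomRecord(serial=i + 1, name="CB", element=element,
                   residue_name=residue_name, chain_id=chain_id,
                   residue_number=i + 1, position=np.asarray(p, float))
        for i, p in enumerate(np.atleast_2d(positions))
    ]
    return AtomicModel(atoms, identifier="protein_cluster")
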