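"""Atomic-model I/O and atom selection.

Models are read from PDB or mmCIF through gemmi into a flat, ordered list of
:class:`AtomRecord`.  Residue numbering is author numbering as deposited — no
renumbering happens on read, so residues can be addressed exactly as
structural papers cite them (e.g. 16S G1307).  Only the first model of a
multi-model file is kept.  Hydrogens and alternate locations are preserved by
I/O; geometry operations downstream reduce to heavy atoms and a single
conformer via :func:`heavy_primary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import ParseError

__all__ = [
    "AtomRecord",
    "AtomicModel",
    "SelectionSpec",
    "read_model",
    "write_model",
    "select",
    "heavy_primary",
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "WATER_NAMES",
]

#: Three-letter codes treated as protein residues (includes common modified
#: residues present in deposited ribosome models).
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
       TRP TYR VAL MSE SEC PYL""".split()
)

#: Residue names treated as nucleic acid (RNA and DNA, plus frequent
#: modified ribonucleotides).
NUCLEOTIDES = frozenset(
    """A U G C I DA DT DG DC DI DU PSU 1MA 2MG 5MC 5MU 7MG M2G OMC OMG UR3""".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


@dataclass
class AtomRecord:
    """One ATOM/HETATM record in author numbering.

    ``position`` is in Å; ``element`` is the upper-case element symbol.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    insertion_code: Optional[str] = None
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    alt_loc: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")
        self.element = self.element.upper()
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"atom {self.serial}: unknown element {self.element!r}")

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element).atomic_number

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    def key(self) -> tuple:
        """Identity of the atom within a model (used for pairing)."""
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.name, self.alt_loc)


@dataclass
class AtomicModel:
    """An ordered collection of atoms with an identifier.

    Iteration order is the file order of the source.  The tuple
    (chain, residue number, insertion code, atom name, alt-loc) is unique.
    """

    atoms: list[AtomRecord]
    identifier: str = ""
    source_format: Optional[str] = None  # "PDB" | "mmCIF" | None (generated)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = a.key()
            if k in seen:
                raise ValueError(f"duplicate atom {k} in model {self.identifier!r}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n, 3) array of positions in file order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])

    def with_atoms(self, atoms: Iterable[AtomRecord], suffix: str = "") -> "AtomicModel":
        return AtomicModel(list(atoms), identifier=self.identifier + suffix,
                           source_format=self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Copy with every position mapped through x ↦ R·x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return AtomicModel(new, identifier=self.identifier, source_format=self.source_format)


def _polymer_class(residue_name: str) -> str:
    if residue_name in AMINO_ACIDS:
        return "protein"
    if residue_name in NUCLEOTIDES:
        return "nucleic"
    return "other"


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunction of per-axis constraints; an unset axis matches everything.

    ``residue_ranges`` are inclusive on both ends, in author numbering, the
    way structural papers cite helix spans.
    """

    chain_ids: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset[str]] = None
    element_filter: Optional[frozenset[str]] = None
    polymer_class: str = "any"  # "protein" | "nucleic" | "any"

    @staticmethod
    def make(chain_ids: Optional[Iterable[str]] = None,
             residue_ranges: Optional[Sequence[Sequence[int]]] = None,
             atom_names: Optional[Iterable[str]] = None,
             element_filter: Optional[Iterable[str]] = None,
             polymer_class: str = "any") -> "SelectionSpec":
        """Build a spec from plain iterables (convenience constructor)."""
        return SelectionSpec(
            chain_ids=frozenset(chain_ids) if chain_ids is not None else None,
            residue_ranges=tuple((int(a), int(b)) for a, b in residue_ranges)
            if residue_ranges is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            element_filter=frozenset(e.upper() for e in element_filter)
            if element_filter is not None else None,
            polymer_class=polymer_class,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_ids is not None and atom.chain_id not in self.chain_ids:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.element_filter is not None and atom.element not in self.element_filter:
            return False
        if self.polymer_class != "any" and _polymer_class(atom.residue_name) != self.polymer_class:
            return False
        return True


def select(model: AtomicModel, spec: SelectionSpec) -> AtomicModel:
    """Sub-model of atoms matching ``spec``, in the original order.

    An all-empty spec returns the full model; an empty result is valid.
    """
    return model.with_atoms([a for a in model.atoms if spec.matches(a)])


def heavy_primary(model: AtomicModel) -> AtomicModel:
    """Reduce to heavy atoms with a single conformer per atom site.

    Alt-loc handling follows the single-conformer convention: the blank
    conformer wins if present; otherwise the highest-occupancy alternate,
    with alt-loc 'A' (alphabetical order) breaking occupancy ties.
    Waters are retained; hydrogens are dropped.
    """
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        site = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        prev = best.get(site)
        if prev is None:
            best[site] = a
            order.append(site)
        else:
            best[site] = _preferred_conformer(prev, a)
    return model.with_atoms([best[s] for s in order])


def _preferred_conformer(x: AtomRecord, y: AtomRecord) -> AtomRecord:
    def rank(a: AtomRecord) -> tuple:
        # blank alt-loc first, then occupancy (desc), then alt-loc letter (asc)
        return (a.alt_loc is not None, -a.occupancy, a.alt_loc or "")
    return min((x, y), key=rank)


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)

_FORMAT_ALIASES = {
    "pdb": "PDB", "ent": "PDB",
    "cif": "mmCIF", "mmcif": "mmCIF",
}


def _normalize_format(fmt: Optional[str], path: Path) -> str:
    if fmt is not None:
        key = fmt.lower().lstrip(".")
        if key not in _FORMAT_ALIASES:
            raise ValueError(f"unsupported model format {fmt!r} (PDB or mmCIF)")
        return _FORMAT_ALIASES[key]
    key = path.suffix.lower().lstrip(".")
    if key in _FORMAT_ALIASES:
        return _FORMAT_ALIASES[key]
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path, format: Optional[str] = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    All ATOM/HETATM records are kept (hydrogens, alternate locations, waters);
    only model 1 of a multi-model file is read.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _normalize_format(format, path)
    coor = gemmi.CoorFormat.Pdb if fmt == "PDB" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path.name}: no models found")
    atoms: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            icode = res.seqid.icode.strip() or None
            het = res.het_flag == "H"
            for at in res:
                if at.element.atomic_number == 0:
                    raise ParseError(
                        f"{path.name}: unknown element for atom {at.serial} "
                        f"({chain.name} {res.name} {res.seqid.num} {at.name})"
                    )
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=float(at.occ),
                    b_factor=float(at.b_iso),
                    is_hetero=het,
                    alt_loc=at.altloc if at.altloc not in ("", " ", "\0") else None,
                ))
    return AtomicModel(atoms, identifier=path.stem, source_format=fmt)


def write_model(model: AtomicModel, path, format: Optional[str] = None) -> None:
    """Write a model as PDB (3-decimal coordinates) or mmCIF.

    Round trip read(write(m)) preserves atom count, names and coordinates to
    the format's precision.
    """
    if not model.atoms:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    fmt = _normalize_format(format, path)
    st = gemmi.Structure()
    st.name = model.identifier or "model"
    gm = gemmi.Model("1")
    chain_obj: dict[str, gemmi.Chain] = {}
    res_key = None
    res_obj = None
    for a in model.atoms:
        if a.chain_id not in chain_obj:
            ch = gemmi.Chain(a.chain_id)
            gm.add_chain(ch)
            chain_obj[a.chain_id] = gm[len(gm) - 1]
        ch = chain_obj[a.chain_id]
        key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        if key != res_key:
            r = gemmi.Residue()
            r.name = a.residue_name
            r.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            r.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(r)
            res_obj = ch[len(ch) - 1]
            res_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.serial = a.serial
        if a.alt_loc:
            at.altloc = a.alt_loc
        res_obj.add_atom(at)
    st.add_model(gm)
    st.setup_entities()
    try:
        if fmt == "PDB":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
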