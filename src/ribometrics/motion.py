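"""Rigid-body domain-motion quantification between two conformations.

The workflow mirrors how ribosome conformational changes are measured in
structural studies: superpose conformation B onto conformation A on a
*reference* selection (e.g. 16S rRNA phosphates of the 30S body), then fit
the *mobile* selection (e.g. 16S head phosphates) of the superposed pair
with a second least-squares rotation.  The mobile rotation's axis–angle form
gives the domain rotation; a twist–swing decomposition about a declared
swivel axis splits it into swivel (twist about the neck axis) and tilt
(residual swing toward the solvent side).

Alignment defaults to one atom per residue — phosphorus for nucleic acids,
alpha-carbon for protein — which makes pairing robust to side-chain and
modelling differences between deposited structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, InsufficientPairsError
from .model_io import AtomicModel, SelectionSpec, heavy_primary, select

__all__ = [
    "RigidTransform",
    "MotionReport",
    "DomainDefinition",
    "pair_atoms",
    "kabsch",
    "domain_rotation",
    "swivel_tilt_decompose",
    "twist_swing",
    "displacement",
    "min_distance",
    "load_domain_definitions",
    "ALIGNMENT_ATOM_NAMES",
]

#: One-atom-per-residue alignment set: P for rRNA backbone, CA for protein.
ALIGNMENT_ATOM_NAMES = frozenset({"P", "CA"})


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation with axis–angle decomposition.

    Maps coordinates ``x`` of the second (mobile) operand onto the first:
    ``x ↦ rotation · x + translation``.  ``angle_deg`` ∈ [0, 180];
    ``axis`` is unit length (arbitrary for the identity).
    """

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)
    angle_deg: float
    axis: np.ndarray  # (3,) unit
    rmsd: float
    n_atoms: int

    @staticmethod
    def from_rt(rotation: np.ndarray, translation: np.ndarray,
                rmsd: float = 0.0, n_atoms: int = 0) -> "RigidTransform":
        rotation = np.asarray(rotation, dtype=float)
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det ≠ +1)")
        rotvec = Rotation.from_matrix(rotation).as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        axis = rotvec / angle if angle > 1e-12 else np.array([0.0, 0.0, 1.0])
        return RigidTransform(rotation=rotation,
                              translation=np.asarray(translation, dtype=float),
                              angle_deg=float(np.degrees(angle)),
                              axis=axis, rmsd=float(rmsd), n_atoms=int(n_atoms))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform.from_rt(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MotionReport:
    """Rigid motion of a mobile domain relative to a reference domain."""

    reference_selection: SelectionSpec
    mobile_selection: SelectionSpec
    body_alignment: RigidTransform
    mobile_motion: RigidTransform
    swivel_deg: float
    tilt_deg: float
    swivel_axis: np.ndarray


@dataclass(frozen=True)
class DomainDefinition:
    """A named rigid domain (e.g. 30S head) as a selection, tagged with the
    rRNA numbering scheme its residue ranges are written in."""

    name: str
    selection: SelectionSpec
    numbering_scheme: str


def pair_atoms(model_a: AtomicModel, model_b: AtomicModel,
               spec: SelectionSpec = SelectionSpec()) -> tuple[np.ndarray, np.ndarray, int]:
    """Match atoms of two models by (chain, residue number, insertion code, name).

    Both models are first reduced to heavy atoms with a single conformer per
    site.  Atoms with no partner are dropped; if insertion codes disagree, a
    residue is still paired when exactly one candidate exists on each side.
    Returns equal-length (n, 3) coordinate arrays (order of model_a) and n.
    """
    sub_a = heavy_primary(select(model_a, spec))
    sub_b = heavy_primary(select(model_b, spec))

    def index(model: AtomicModel) -> dict:
        d: dict[tuple, list] = {}
        for a in model:
            d.setdefault((a.chain_id, a.residue_number, a.insertion_code, a.name),
                         []).append(a)
        return d

    def loose_index(model: AtomicModel) -> dict:
        d: dict[tuple, list] = {}
        for a in model:
            d.setdefault((a.chain_id, a.residue_number, a.name), []).append(a)
        return d

    idx_b = index(sub_b)
    loose_b = loose_index(sub_b)
    pa, pb = [], []
    for a in sub_a:
        exact = idx_b.get((a.chain_id, a.residue_number, a.insertion_code, a.name), [])
        if len(exact) == 1:
            partner = exact[0]
        else:
            loose = loose_b.get((a.chain_id, a.residue_number, a.name), [])
            if len(loose) != 1:
                continue  # ambiguous or absent
            partner = loose[0]
        pa.append(a.position)
        pb.append(partner.position)
    n = len(pa)
    if n < 3:
        raise InsufficientPairsError(f"only {n} atom pairs matched; need ≥ 3")
    return np.array(pa), np.array(pb), n


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition mapping ``coords_b`` onto ``coords_a``.

    Classic SVD solution with the reflection corrected by a sign flip of the
    smallest singular direction, so the result is always a proper rotation.
    Collinear or coincident point sets are rejected.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise InsufficientPairsError(f"need ≥ 3 point pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(A - ca), np.linalg.norm(B - cb), 1e-300)
    if S[1] <= 1e-10 * scale**2 / n + 1e-300:
        raise DegenerateInputError("point sets are collinear or coincident; "
                                   "rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    rmsd = float(np.sqrt(np.mean(np.sum((B @ R.T + t - A) ** 2, axis=1))))
    return RigidTransform.from_rt(R, t, rmsd=rmsd, n_atoms=n)


def _alignment_spec(spec: SelectionSpec) -> SelectionSpec:
    """Fill in the default one-atom-per-residue alignment atoms when unset."""
    if spec.atom_names is None:
        return SelectionSpec(chain_ids=spec.chain_ids,
                             residue_ranges=spec.residue_ranges,
                             atom_names=ALIGNMENT_ATOM_NAMES,
                             element_filter=spec.element_filter,
                             polymer_class=spec.polymer_class)
    return spec


def domain_rotation(model_a: AtomicModel, model_b: AtomicModel,
                    reference: SelectionSpec, mobile: SelectionSpec,
                    swivel_axis: Optional[np.ndarray] = None,
                    alignment_atoms: bool = True) -> MotionReport:
    """Rotation of a mobile domain between two conformations.

    model_b is globally superposed onto model_a on the reference selection;
    the mobile selection of the superposed pair is then fitted to give the
    domain motion.  When ``swivel_axis`` is None the motion's own rotation
    axis is used, so swivel equals the full angle and tilt is 0 — pass the
    frozen canonical axis to get a meaningful split.

    With ``alignment_atoms`` (default) selections without explicit atom
    names are restricted to P/CA.
    """
    ref = _alignment_spec(reference) if alignment_atoms else reference
    mob = _alignment_spec(mobile) if alignment_atoms else mobile
    ra, rb, _ = pair_atoms(model_a, model_b, ref)
    body = kabsch(ra, rb)
    ma, mb, _ = pair_atoms(model_a, model_b, mob)
    mb_aligned = body.apply(mb)
    mobile_motion = kabsch(ma, mb_aligned)
    if swivel_axis is None:
        axis = mobile_motion.axis
    else:
        axis = np.asarray(swivel_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    swivel_deg, tilt_deg = swivel_tilt_decompose(mobile_motion, axis)
    return MotionReport(reference_selection=reference, mobile_selection=mobile,
                        body_alignment=body, mobile_motion=mobile_motion,
                        swivel_deg=swivel_deg, tilt_deg=tilt_deg, swivel_axis=axis)


def twist_swing(rotation: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a rotation R into R = R_swing · R_twist.

    R_twist is the rotation about ``axis`` (the quaternion projection onto
    the axis); R_swing is the residual rotation, whose axis is orthogonal to
    ``axis``.  The product reconstructs R to machine precision.
    """
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    q = Rotation.from_matrix(np.asarray(rotation, dtype=float)).as_quat()  # x,y,z,w
    p = float(q[:3] @ u)
    w = float(q[3])
    nrm = np.hypot(p, w)
    if nrm < 1e-12:
        # pure 180° swing: no twist component is defined; take identity twist
        twist = Rotation.identity()
    else:
        twist = Rotation.from_quat(np.array([*(u * p / nrm), w / nrm]))
    R_twist = twist.as_matrix()
    R_swing = np.asarray(rotation) @ R_twist.T
    return R_twist, R_swing


def swivel_tilt_decompose(motion: Union[RigidTransform, np.ndarray],
                          swivel_axis: np.ndarray) -> tuple[float, float]:
    """(swivel°, tilt°): twist about the swivel axis and residual swing.

    Both angles are reported as non-negative magnitudes; a zero rotation
    returns (0, 0).
    """
    R = motion.rotation if isinstance(motion, RigidTransform) else np.asarray(motion)
    R_twist, R_swing = twist_swing(R, swivel_axis)
    swivel = np.degrees(np.linalg.norm(Rotation.from_matrix(R_twist).as_rotvec()))
    tilt = np.degrees(np.linalg.norm(Rotation.from_matrix(R_swing).as_rotvec()))
    return float(swivel), float(tilt)


def displacement(model_a: AtomicModel, model_b: AtomicModel,
                 measure: SelectionSpec, align_on: SelectionSpec,
                 statistic: str = "mean"):
    """Per-atom displacements of ``measure`` after superposition on ``align_on``.

    ``statistic`` is "mean" or "max" (a float, Å) or "per_residue" (a dict
    mapping (chain, residue number) to the mean displacement of that
    residue's paired atoms).
    """
    if statistic not in ("mean", "max", "per_residue"):
        raise ValueError(f"unknown statistic {statistic!r}")
    ra, rb, _ = pair_atoms(model_a, model_b, _alignment_spec(align_on))
    body = kabsch(ra, rb)
    sub_a = heavy_primary(select(model_a, measure))
    sub_b = heavy_primary(select(model_b, measure))
    # measured selection pairs all heavy atoms (not P/CA only) and may be small
    ma, mb, n = _pair_small(sub_a, sub_b)
    dists = np.linalg.norm(body.apply(mb) - ma, axis=1)
    if statistic == "mean":
        return float(dists.mean())
    if statistic == "max":
        return float(dists.max())
    per: dict[tuple, list] = {}
    keys = _paired_keys(sub_a, sub_b)
    for k, d in zip(keys, dists):
        per.setdefault(k, []).append(d)
    return {k: float(np.mean(v)) for k, v in per.items()}


def _pair_small(sub_a: AtomicModel, sub_b: AtomicModel) -> tuple[np.ndarray, np.ndarray, int]:
    """Pairing for measured selections that may have fewer than 3 atoms."""
    idx = {a.key()[:4]: a for a in sub_b}
    pa = [a.position for a in sub_a if (a.chain_id, a.residue_number,
                                        a.insertion_code, a.name) in idx]
    pb = [idx[(a.chain_id, a.residue_number, a.insertion_code, a.name)].position
          for a in sub_a if (a.chain_id, a.residue_number,
                             a.insertion_code, a.name) in idx]
    if not pa:
        raise InsufficientPairsError("no atoms of the measured selection paired")
    return np.array(pa), np.array(pb), len(pa)


def _paired_keys(sub_a: AtomicModel, sub_b: AtomicModel) -> list[tuple]:
    keys_b = {(a.chain_id, a.residue_number, a.insertion_code, a.name) for a in sub_b}
    out = []
    for a in sub_a:
        k = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        if k in keys_b:
            out.append((a.chain_id, a.residue_number))
    return out


def min_distance(model: AtomicModel, sel_a: SelectionSpec, sel_b: SelectionSpec) -> float:
    """Minimum pairwise heavy-atom distance (Å) between two selections."""
    a = heavy_primary(select(model, sel_a))
    b = heavy_primary(select(model, sel_b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both selections must be non-empty")
    tree = cKDTree(b.coordinates())
    d, _ = tree.query(a.coordinates(), k=1)
    return float(np.min(d))


def load_domain_definitions(scheme: str = "Ecoli-16S",
                            path=None) -> dict[str, DomainDefinition]:
    """Load named 16S domain boundaries for a numbering scheme.

    Ships with 'Ecoli-16S' (head = 3'-major domain, residues 930–1390) and
    'Sac-16S' (the same boundaries ported with the piecewise offsets anchored
    on Sac G1307 ↔ E. coli G1338 and Sac G496 ↔ E. coli G530).  Sibling
    domains within a scheme are validated to be disjoint.
    """
    if path is None:
        text = resources.files("ribometrics.data").joinpath("domains_16s.yaml").read_text()
    else:
        text = open(path).read()
    doc = yaml.safe_load(text)
    schemes = doc["schemes"]
    if scheme not in schemes:
        raise KeyError(f"unknown numbering scheme {scheme!r}; "
                       f"available: {sorted(schemes)}")
    out: dict[str, DomainDefinition] = {}
    covered: list[tuple[str, int, int]] = []
    for name, entry in schemes[scheme].items():
        ranges = tuple((int(a), int(b)) for a, b in entry["residue_ranges"])
        for lo, hi in ranges:
            for (other, olo, ohi) in covered:
                if lo <= ohi and olo <= hi:
                    raise ValueError(f"domains {other!r} and {name!r} overlap "
                                     f"in scheme {scheme!r}")
            covered.append((name, lo, hi))
        out[name] = DomainDefinition(
            name=name,
            selection=SelectionSpec.make(residue_ranges=ranges,
                                         polymer_class="nucleic"),
            numbering_scheme=scheme,
        )
    return out
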