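"""Seeded toy fixtures: helical models, conformational pairs with known
rigid motions, and density maps with a known true but mislabelled pixel size.

These emulate, at desk scale, the objects the real analyses run on: a
two-domain rRNA-like particle standing in for the 30S body/head, and a map
whose header voxel size differs from the size it was actually generated at
(the miscalibrated-magnification scenario).  Every generated quantity is
returned as ground truth so the corresponding analysis can be tested as a
parameter-recovery problem.

A single integer seed drives one ``numpy.random.default_rng`` stream per
call; identical specs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import rescale_geometry
from .density import DensityMap, SimulationParams, simulate_map
from .model_io import AtomicModel, AtomRecord, SelectionSpec
from .motion import MotionReport, RigidTransform

__all__ = [
    "ToySpec",
    "make_helix_model",
    "make_two_domain_pair",
    "make_mislabelled_map",
]

# ideal helix geometries (rise Å, twist °/residue, radius Å)
_HELIX_GEOMETRY = {
    "protein_alpha_helix": (1.5, 100.0, 2.3, "CA", "C",
                            ("LEU", "ALA")),
    "rna_P_trace": (2.81, 32.7, 8.8, "P", "P", ("A", "U")),
}


@dataclass(frozen=True)
class ToySpec:
    """Conditions for a generated fixture.

    Defaults reproduce the scenario the analyses target: an 18° head
    rotation (the full chimeric→POST head swivel), maps simulated at
    3.5 Å resolution, a true pixel size of 1.057 Å inside the
    1.047–1.087 sweep window, and a nominal header value of 1.087 Å.
    """

    n_domains: int = 2
    atoms_per_domain: int = 60
    swivel_deg: float = 18.0
    tilt_deg: float = 0.0
    swivel_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tilt_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    head_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    coordinate_noise_sigma: float = 0.0
    true_voxel: float = 1.057
    labelled_voxel: float = 1.087
    map_noise_sigma: float = 0.0  # fraction of the peak density
    resolution: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_voxel <= 0 or self.labelled_voxel <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.n_domains < 1 or self.atoms_per_domain < 1:
            raise ValueError("need at least one domain and one atom per domain")


def make_helix_model(n_residues: int, kind: str = "rna_P_trace",
                     chain_id: str = "A", start_residue: int = 1,
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                     identifier: str = "helix") -> AtomicModel:
    """Ideal helical one-atom-per-residue trace.

    'protein_alpha_helix': CA atoms, rise 1.5 Å, twist 100°/residue,
    radius 2.3 Å, residues cycling LEU/ALA.  'rna_P_trace': P atoms of an
    A-form-like helix, rise 2.81 Å, twist 32.7°/residue, radius 8.8 Å,
    residues cycling A/U.  Real residue names are used so selection and
    burial logic run unmodified on fixtures.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be ≥ 1")
    if kind not in _HELIX_GEOMETRY:
        raise ValueError(f"unknown helix kind {kind!r}")
    rise, twist, radius, atom_name, element, res_names = _HELIX_GEOMETRY[kind]
    org = np.asarray(origin, dtype=float)
    atoms = []
    for k in range(n_residues):
        ang = np.radians(twist * k)
        pos = org + np.array([radius * np.cos(ang), radius * np.sin(ang), rise * k])
        atoms.append(AtomRecord(
            serial=k + 1,
            name=atom_name,
            element=element,
            residue_name=res_names[k % len(res_names)],
            chain_id=chain_id,
            residue_number=start_residue + k,
            position=pos,
        ))
    return AtomicModel(atoms, identifier=identifier)


def _rotation_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    return Rotation.from_rotvec(np.radians(deg) * axis / n).as_matrix()


def make_two_domain_pair(spec: ToySpec) -> tuple[AtomicModel, AtomicModel, MotionReport]:
    """A body+head particle and a second conformation with a known head motion.

    The body is an RNA P-trace (residues 1..n of chain A); the head is a
    second P-trace stacked above it (residues n+1..2n).  Conformation B
    applies, about the head centroid, the rotation
    R = R_tilt(tilt_deg) · R_swivel(swivel_deg) — swing-after-twist, the
    same convention the twist–swing decomposition inverts — plus an optional
    translation, then Gaussian coordinate noise on all atoms of B.
    The returned ground truth carries the selections, the composed rotation
    and the swivel/tilt split.
    """
    n = spec.atoms_per_domain
    body = make_helix_model(n, "rna_P_trace", chain_id="A", start_residue=1,
                            identifier="toy")
    head = make_helix_model(n, "rna_P_trace", chain_id="A", start_residue=n + 1,
                            origin=(0.0, 0.0, 2.81 * n + 6.0),
                            identifier="toy")
    model_a = AtomicModel(body.atoms + [_renumber_serial(a, n + i + 1)
                                        for i, a in enumerate(head.atoms)],
                          identifier="toy_a")

    u = np.asarray(spec.swivel_axis, dtype=float)
    u = u / np.linalg.norm(u)
    t_axis = np.asarray(spec.tilt_axis, dtype=float)
    t_axis = t_axis - (t_axis @ u) * u  # enforce orthogonality to the swivel axis
    if np.linalg.norm(t_axis) < 1e-12:
        raise ValueError("tilt_axis must not be parallel to swivel_axis")
    R = (_rotation_about(t_axis, spec.tilt_deg)
         @ _rotation_about(u, spec.swivel_deg))
    head_coords = np.stack([a.position for a in model_a.atoms[n:]])
    centroid = head_coords.mean(axis=0)
    shift = np.asarray(spec.head_translation, dtype=float)

    rng = np.random.default_rng(spec.seed)
    atoms_b = []
    for i, a in enumerate(model_a.atoms):
        p = a.position
        if i >= n:  # head atom
            p = R @ (p - centroid) + centroid + shift
        if spec.coordinate_noise_sigma > 0:
            p = p + rng.normal(0.0, spec.coordinate_noise_sigma, 3)
        atoms_b.append(AtomRecord(
            serial=a.serial, name=a.name, element=a.element,
            residue_name=a.residue_name, chain_id=a.chain_id,
            residue_number=a.residue_number, position=p,
        ))
    model_b = AtomicModel(atoms_b, identifier="toy_b")

    body_sel = SelectionSpec.make(residue_ranges=[(1, n)])
    head_sel = SelectionSpec.make(residue_ranges=[(n + 1, 2 * n)])
    truth_motion = RigidTransform.from_rt(R, centroid - R @ centroid + shift,
                                          rmsd=0.0, n_atoms=n)
    truth = MotionReport(
        reference_selection=body_sel,
        mobile_selection=head_sel,
        body_alignment=RigidTransform.identity(),
        mobile_motion=truth_motion,
        swivel_deg=abs(spec.swivel_deg),
        tilt_deg=abs(spec.tilt_deg),
        swivel_axis=u,
    )
    return model_a, model_b, truth


def _renumber_serial(a: AtomRecord, serial: int) -> AtomRecord:
    return AtomRecord(serial=serial, name=a.name, element=a.element,
                      residue_name=a.residue_name, chain_id=a.chain_id,
                      residue_number=a.residue_number, position=a.position.copy())


def make_mislabelled_map(model: AtomicModel, spec: ToySpec) -> DensityMap:
    """Simulate a map at ``true_voxel`` and relabel its header geometry to
    ``labelled_voxel``, keeping the map center fixed.

    This reproduces the miscalibrated-magnification scenario: the data are
    self-consistent in pixel units, but the header's Å/pixel is wrong, so
    the world-coordinate frame is scaled relative to the docked model.
    Optional Gaussian voxel noise with standard deviation
    ``map_noise_sigma × peak`` is added from the spec's seed.
    """
    sim = simulate_map(model, SimulationParams(resolution=spec.resolution,
                                               voxel_size=spec.true_voxel))
    out = rescale_geometry(sim, spec.labelled_voxel / spec.true_voxel)
    grid = out.grid.astype(np.float64)
    if spec.map_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        grid = grid + rng.normal(0.0, spec.map_noise_sigma * grid.max(), grid.shape)
    return DensityMap(grid, out.voxel_size, out.origin,
                      identifier=f"mislabelled({model.identifier})")
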