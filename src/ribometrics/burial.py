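"""Solvent accessibility and the buried-hydrophobic-atom statistic.

Thermophilic ribosomal subunits pack more hydrophobic residue atoms away
from solvent than mesophilic ones; the statistic quantified here counts
carbon/sulfur atoms of hydrophobic protein residues whose solvent-accessible
surface area (SASA) falls below a burial threshold, with SASA evaluated in
the context of the full assembly (rRNA and other heteroatoms occlude, waters
are stripped, but only r-protein atoms are counted).

SASA uses the Shrake–Rupley construction with a deterministic golden-section
spiral point set, so results are bit-reproducible: the same quasi-uniform
points are placed on every atom's probe-expanded sphere, and a point counts
as accessible iff it lies outside every neighbour's expanded sphere.  The
neighbour search is pruned with a KD-tree using a radius bound that makes it
provably identical to the all-pairs scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .model_io import AMINO_ACIDS, AtomicModel, heavy_primary

__all__ = [
    "SasaParams",
    "BurialReport",
    "sasa",
    "sasa_atoms",
    "count_buried_hydrophobic",
    "burial_excess",
    "sphere_points",
    "load_vdw_radii",
    "HYDROPHOBIC_RESIDUES",
]

HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO",
                                  "PHE", "MET", "TRP"})

_DEFAULT_RADII: Optional[dict[str, float]] = None


def load_vdw_radii(path=None) -> dict[str, float]:
    """Element → van der Waals radius (Å) table shipped as package data."""
    global _DEFAULT_RADII
    if path is None:
        if _DEFAULT_RADII is None:
            text = resources.files("ribometrics.data").joinpath("vdw_radii.yaml").read_text()
            _DEFAULT_RADII = {str(k).upper(): float(v)
                              for k, v in yaml.safe_load(text).items()}
        return _DEFAULT_RADII
    return {str(k).upper(): float(v) for k, v in yaml.safe_load(open(path)).items()}


@dataclass(frozen=True)
class SasaParams:
    """Free parameters of the burial statistic.

    burial is absolute (SASA < burial_threshold Å²) by default; set
    ``relative`` to classify by SASA < relative_fraction × isolated area
    instead.
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radius_set: Optional[dict[str, float]] = None  # None → shipped table
    burial_threshold: float = 0.1
    hydrophobic_residues: frozenset = HYDROPHOBIC_RESIDUES
    counted_elements: frozenset = frozenset({"C", "S"})
    relative: bool = False
    relative_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.probe_radius < 0 or self.burial_threshold < 0:
            raise ValueError("probe_radius and burial_threshold must be ≥ 0")
        if self.n_sphere_points < 16:
            raise ValueError("n_sphere_points must be ≥ 16")

    def radii(self) -> dict[str, float]:
        return self.radius_set if self.radius_set is not None else load_vdw_radii()


@dataclass
class BurialReport:
    """Per-atom accessibility plus the hydrophobic-burial counts.

    ``atoms`` is the occluder sub-model (heavy, single-conformer, waterless)
    that ``per_atom_sasa`` is aligned with.  ``buried_hydrophobic_residue_count``
    counts hydrophobic residues whose counted atoms are *all* buried.
    """

    atoms: AtomicModel
    per_atom_sasa: np.ndarray
    hydrophobic_atom_count: int
    buried_hydrophobic_count: int
    total_sasa: float
    buried_hydrophobic_residue_count: int = 0
    hydrophobic_residue_count: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.buried_hydrophobic_count
                <= self.hydrophobic_atom_count <= len(self.atoms)):
            raise ValueError("inconsistent burial counts")
        if np.any(self.per_atom_sasa < 0):
            raise ValueError("negative SASA")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa_atoms(model: AtomicModel) -> AtomicModel:
    """The sub-model SASA operates on: heavy atoms, one conformer, no waters."""
    sub = heavy_primary(model)
    return sub.with_atoms([a for a in sub if not a.is_water])


def sasa(model: AtomicModel, params: SasaParams = SasaParams()) -> np.ndarray:
    """Shrake–Rupley solvent-accessible area (Å²) per atom of
    :func:`sasa_atoms`(model), in that sub-model's order."""
    sub = sasa_atoms(model)
    if len(sub) == 0:
        raise ValueError("model has no heavy non-water atoms")
    radii_table = params.radii()
    try:
        r = np.array([radii_table[a.element] for a in sub])
    except KeyError as exc:
        raise ConfigurationError(f"no van der Waals radius for element "
                                 f"{exc.args[0]!r}") from exc
    pos = sub.coordinates()
    R = r + params.probe_radius  # expanded radii
    pts = sphere_points(params.n_sphere_points)
    tree = cKDTree(pos)
    rmax = float(R.max())
    areas = np.empty(len(sub))
    for i in range(len(sub)):
        # any occluder of a point on sphere i satisfies |ci−cj| < Ri + Rj
        nbrs = [j for j in tree.query_ball_point(pos[i], R[i] + rmax) if j != i]
        surface = pos[i] + R[i] * pts
        accessible = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = np.sum((surface - pos[j]) ** 2, axis=1)
            accessible &= d2 >= R[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * math.pi * R[i] ** 2
    return areas


def count_buried_hydrophobic(model: AtomicModel,
                             params: SasaParams = SasaParams()) -> BurialReport:
    """Count buried hydrophobic r-protein atoms in the context of the
    full model (rRNA and heteroatoms occlude; waters are excluded)."""
    sub = sasa_atoms(model)
    if not any(a.residue_name in AMINO_ACIDS for a in sub):
        raise ValueError("model contains no protein residues; "
                         "the burial statistic is defined over r-proteins")
    areas = sasa(model, params)
    radii_table = params.radii()
    counted = np.array([a.residue_name in params.hydrophobic_residues
                        and a.element in params.counted_elements
                        for a in sub])
    if params.relative:
        iso = np.array([4.0 * math.pi * (radii_table[a.element] + params.probe_radius) ** 2
                        for a in sub])
        buried_mask = areas < params.relative_fraction * iso
    else:
        buried_mask = areas < params.burial_threshold
    buried = counted & buried_mask
    # residue-level view: a hydrophobic residue is buried iff every one of
    # its counted atoms is buried
    res_total: dict[tuple, int] = {}
    res_buried: dict[tuple, int] = {}
    for a, c, bmask in zip(sub, counted, buried):
        if not c:
            continue
        key = (a.chain_id, a.residue_number, a.insertion_code)
        res_total[key] = res_total.get(key, 0) + 1
        res_buried[key] = res_buried.get(key, 0) + int(bmask)
    n_res = len(res_total)
    n_res_buried = sum(1 for k in res_total if res_buried[k] == res_total[k])
    return BurialReport(
        atoms=sub,
        per_atom_sasa=areas,
        hydrophobic_atom_count=int(counted.sum()),
        buried_hydrophobic_count=int(buried.sum()),
        total_sasa=float(areas.sum()),
        buried_hydrophobic_residue_count=n_res_buried,
        hydrophobic_residue_count=n_res,
    )


def burial_excess(report_a: BurialReport, report_b: BurialReport) -> float:
    """Percent excess of buried hydrophobic atoms of a over b:
    100 × (a.buried − b.buried) / b.buried."""
    if report_b.buried_hydrophobic_count <= 0:
        raise ValueError("baseline report has zero buried hydrophobic atoms")
    a = report_a.buried_hydrophobic_count
    b = report_b.buried_hydrophobic_count
    return 100.0 * (a - b) / b
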