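"""Pixel-size calibration by map–model correlation sweep.

Cryo-EM magnification is only nominally calibrated: the voxel (pixel) size
recorded in a map header can be off by a percent or more, which scales every
distance measured in the map.  When an independently refined atomic model is
docked into the map, the true pixel size can be recovered by sweeping
candidate values, rescaling the map's coordinate frame accordingly, and
correlating the experimental density against a map simulated from the model:
the correlation peaks where the scale is right.

The sweep never interpolates the experimental data.  A candidate pixel size
``s`` rescales the experimental map's *geometry* (metadata) by ``s/nominal``
about the map center; the simulated model map is the one resampled onto that
geometry.  This preserves the experimental values bit-exactly and mirrors
how fitting tools treat pixel size as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .density import DensityMap, GridGeometry, SimulationParams, correlate, resample, simulate_map
from .errors import DegenerateInputError
from .model_io import AtomicModel, heavy_primary

__all__ = [
    "CalibrationCurve",
    "calibrate_pixel_size",
    "rescale_geometry",
    "overlap_fraction",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Result of a pixel-size sweep.

    ``candidate_voxels`` are strictly increasing; ``optimum_voxel`` lies in
    their range.  In ``argmax`` mode the optimum is the candidate attaining
    the maximum correlation; in ``parabolic`` mode it is the vertex of a
    parabola through the top three points, clamped to the sweep range.
    """

    nominal_voxel: float
    candidate_voxels: tuple[float, ...]
    correlations: tuple[float, ...]
    optimum_voxel: float
    optimum_mode: str  # "argmax" | "parabolic"
    correlation_mode: str = "about_zero"

    def __post_init__(self) -> None:
        cv = np.asarray(self.candidate_voxels)
        if len(cv) != len(self.correlations):
            raise ValueError("candidate/correlation length mismatch")
        if np.any(np.diff(cv) <= 0):
            raise ValueError("candidate_voxels must be strictly increasing")
        if not (cv[0] - 1e-12 <= self.optimum_voxel <= cv[-1] + 1e-12):
            raise ValueError("optimum_voxel outside the sweep range")

    def as_table(self) -> str:
        """TSV table: candidate_voxel <tab> correlation."""
        lines = ["candidate_voxel\tcorrelation"]
        lines += [f"{v:.4f}\t{c:.4f}"
                  for v, c in zip(self.candidate_voxels, self.correlations)]
        return "\n".join(lines)


def rescale_geometry(density_map: DensityMap, factor: float) -> DensityMap:
    """Multiply the voxel size by ``factor``, keeping the map center fixed.

    Grid values are untouched; only the metadata changes.  The geometric
    center being the fixed point minimizes drift of a centered particle.
    """
    if factor <= 0:
        raise ValueError(f"rescale factor must be positive, got {factor}")
    center = density_map.geometry.center()
    new_voxel = density_map.voxel_size * factor
    new_origin = center - (center - density_map.origin) * factor
    return DensityMap(density_map.grid, new_voxel, new_origin,
                      identifier=density_map.identifier)


def overlap_fraction(density_map: DensityMap, model: AtomicModel) -> float:
    """Fraction of the model's heavy atoms inside the map footprint.

    A mis-docked model shows up as a low value before any sweep is run.
    """
    sub = heavy_primary(model)
    if len(sub) == 0:
        return 0.0
    pos = sub.coordinates()
    nz, ny, nx = density_map.grid.shape
    lo = density_map.origin - density_map.voxel_size / 2
    hi = density_map.origin + (np.array([nx, ny, nz]) - 0.5) * density_map.voxel_size
    inside = np.all((pos >= lo) & (pos <= hi), axis=1)
    return float(inside.mean())


def _candidates(sweep: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = sweep
    if not (lo < hi and step > 0):
        raise ValueError(f"invalid sweep {sweep}: need min < max and step > 0")
    n = int(round((hi - lo) / step)) + 1
    cand = lo + step * np.arange(n)
    cand = cand[cand <= hi + 1e-9]
    if len(cand) < 2:
        raise ValueError(f"sweep {sweep} yields fewer than 2 candidates")
    return cand


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through points i−1, i, i+1."""
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # flat or concave-up triple: keep the grid point
        return float(x[i])
    step = (x[i + 1] - x[i - 1]) / 2.0
    return float(x[i] + 0.5 * step * (y[i - 1] - y[i + 1]) / denom)


def calibrate_pixel_size(exp_map: DensityMap, model: AtomicModel,
                         sweep: tuple[float, float, float] = (1.047, 1.087, 0.01),
                         sim_params: Optional[SimulationParams] = None,
                         corr_mode: str = "about_zero",
                         mask_threshold: float = 0.0,
                         refine: bool = False,
                         nominal_voxel: Optional[float] = None) -> CalibrationCurve:
    """Sweep candidate pixel sizes and return the correlation curve + optimum.

    The model must already be docked in the experimental map's frame.
    ``nominal_voxel`` defaults to the map header's voxel size; pass it
    explicitly when the header already carries a corrected value and the
    sweep should be interpreted against the original nominal one.
    """
    cand = _candidates(sweep)
    if nominal_voxel is None:
        vs = exp_map.voxel_size
        if not np.allclose(vs, vs[0], atol=1e-9):
            raise ValueError("anisotropic voxel size; pass nominal_voxel explicitly")
        nominal_voxel = float(vs[0])
    if sim_params is None:
        sim_params = SimulationParams(voxel_size=nominal_voxel)
    sim = simulate_map(model, sim_params)
    correlations = []
    any_mask = False
    for s in cand:
        rescaled = rescale_geometry(exp_map, float(s) / nominal_voxel)
        sim_on_exp = resample(sim, rescaled.geometry)
        try:
            c = correlate(rescaled, sim_on_exp, mode=corr_mode,
                          mask_threshold=mask_threshold)
            any_mask = True
        except DegenerateInputError:
            c = np.nan
        correlations.append(c)
    corr = np.asarray(correlations)
    if not any_mask or np.all(np.isnan(corr)):
        raise DegenerateInputError(
            "model density does not overlap the map footprint at any sweep scale; "
            f"check docking (overlap fraction {overlap_fraction(exp_map, model):.2f})")
    corr = np.nan_to_num(corr, nan=-1.0)
    i = int(np.argmax(corr))
    if refine and 0 < i < len(cand) - 1:
        opt = _parabolic_vertex(cand, corr, i)
        opt = float(np.clip(opt, cand[0], cand[-1]))
        mode = "parabolic"
    else:
        opt = float(cand[i])
        mode = "parabolic" if refine else "argmax"
    return CalibrationCurve(
        nominal_voxel=float(nominal_voxel),
        candidate_voxels=tuple(float(v) for v in cand),
        correlations=tuple(float(c) for c in corr),
        optimum_voxel=opt,
        optimum_mode=mode,
        correlation_mode=corr_mode,
    )
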