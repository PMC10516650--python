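"""Density maps: MRC/CCP4 I/O, simulation from atoms, resampling, correlation.

The in-memory convention is fixed regardless of file axis order: ``grid`` is
indexed (z, y, x), ``voxel_size`` and ``origin`` are (x, y, z) triples in Å,
and the world coordinate of voxel (i, j, k) is
``origin + (k·vx, j·vy, i·vz)``.

Map simulation places an isotropic Gaussian on every heavy atom with
σ = sigma_factor × resolution (default sigma_factor 0.225 = 1/(π√2), the
convention under which the Fourier transform of the kernel falls to 1/e of
its maximum at spatial frequency 1/resolution).  Amplitudes are proportional
to atomic number by default, so the simulated density approximates a
low-resolution electron-scattering picture without per-element form factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateInputError, MapFormatError
from .model_io import AtomicModel, heavy_primary

__all__ = [
    "GridGeometry",
    "DensityMap",
    "SimulationParams",
    "read_map",
    "write_map",
    "simulate_map",
    "resample",
    "correlate",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shape (nz, ny, nx), per-axis voxel size (x, y, z) and origin (x, y, z)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def axes_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along (z, y, x) axes."""
        nz, ny, nx = self.shape
        vx, vy, vz = self.voxel_size
        ox, oy, oz = self.origin
        return (oz + vz * np.arange(nz),
                oy + vy * np.arange(ny),
                ox + vx * np.arange(nx))

    def center(self) -> np.ndarray:
        """World coordinate (x, y, z) of the geometric center of the grid."""
        nz, ny, nx = self.shape
        n_xyz = np.array([nx, ny, nz], dtype=float)
        return np.asarray(self.origin) + (n_xyz - 1) / 2.0 * np.asarray(self.voxel_size)


@dataclass
class DensityMap:
    """A 3-D scalar field on a regular grid."""

    grid: np.ndarray  # (nz, ny, nx)
    voxel_size: np.ndarray  # (vx, vy, vz), Å/pixel
    origin: np.ndarray  # (ox, oy, oz), Å — center of voxel (0,0,0)
    identifier: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D (z, y, x)")
        self.voxel_size = np.array(self.voxel_size, dtype=float) * np.ones(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.grid.shape),
                            tuple(self.voxel_size), tuple(self.origin))

    def same_geometry(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.grid.shape == other.grid.shape
                and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of Gaussian map simulation.

    resolution and voxel_size are in Å; padding extends the grid beyond the
    model bounding box.  amplitude_mode 'atomic_number' weights each atom by
    Z, 'unit' weights all atoms equally (useful for synthetic point tests).
    """

    resolution: float = 3.5
    voxel_size: float = 1.0
    padding: float = 5.0
    amplitude_mode: str = "atomic_number"  # or "unit"
    sigma_factor: float = 1.0 / (math.pi * math.sqrt(2.0))  # ≈ 0.22508
    cutoff_sigmas: float = 4.5

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.voxel_size <= 0 or self.padding < 0:
            raise ValueError("resolution and voxel_size must be > 0, padding ≥ 0")
        if self.amplitude_mode not in ("atomic_number", "unit"):
            raise ValueError(f"unknown amplitude_mode {self.amplitude_mode!r}")

    @property
    def sigma(self) -> float:
        return self.sigma_factor * self.resolution


def simulate_map(model: AtomicModel, params: SimulationParams = SimulationParams(),
                 geometry: Optional[GridGeometry] = None) -> DensityMap:
    """Simulate a density map from a model's heavy atoms.

    Each atom contributes amplitude · exp(−d²/2σ²); the sum is linear in the
    atom set, so simulating a union of models on one ``geometry`` equals the
    sum of the parts simulated on that geometry.  The kernel is truncated at
    ``cutoff_sigmas``·σ (default 4.5σ, where the Gaussian is below 4·10⁻⁵ of
    its peak).  When ``geometry`` is None the grid covers the model bounding
    box plus ``params.padding`` at ``params.voxel_size``; an anisotropic
    explicit geometry is honoured as given.
    """
    sub = heavy_primary(model)
    if len(sub) == 0:
        raise ValueError("model has no heavy atoms to simulate")
    pos = sub.coordinates()
    if params.amplitude_mode == "atomic_number":
        amps = np.array([a.atomic_number for a in sub], dtype=float)
    else:
        amps = np.ones(len(sub))
    if geometry is None:
        v = np.full(3, params.voxel_size)
        lo = pos.min(axis=0) - params.padding
        hi = pos.max(axis=0) + params.padding
        n_xyz = np.ceil((hi - lo) / v).astype(int) + 1
        origin = lo
        nz, ny, nx = int(n_xyz[2]), int(n_xyz[1]), int(n_xyz[0])
    else:
        v = np.asarray(geometry.voxel_size, dtype=float)
        origin = np.asarray(geometry.origin, dtype=float)
        nz, ny, nx = geometry.shape
    grid = np.zeros((nz, ny, nx), dtype=np.float64)
    sigma = params.sigma
    cut = params.cutoff_sigmas * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    n_axis = np.array([nx, ny, nz])
    for p, amp in zip(pos, amps):
        i0 = np.maximum(np.ceil((p - cut - origin) / v).astype(int), 0)
        i1 = np.minimum(np.floor((p + cut - origin) / v).astype(int), n_axis - 1)
        if np.any(i1 < i0):
            continue  # atom (plus cutoff) entirely outside the grid
        ax = [origin[d] + v[d] * np.arange(i0[d], i1[d] + 1) for d in range(3)]
        ker = [np.exp(-((ax[d] - p[d]) ** 2) * inv2s2) for d in range(3)]
        local = amp * ker[2][:, None, None] * ker[1][None, :, None] * ker[0][None, None, :]
        grid[i0[2]:i1[2] + 1, i0[1]:i1[1] + 1, i0[0]:i1[0] + 1] += local
    return DensityMap(grid, v, origin, identifier=f"sim({model.identifier})")


def resample(source: DensityMap, target: GridGeometry) -> DensityMap:
    """Trilinear interpolation of ``source`` at the voxel centers of ``target``.

    Points outside the source footprint evaluate to 0, so shrinking or
    growing sweeps never raise; edge voxels are handled by the correlation
    mask downstream.
    """
    sz, sy, sx = source.geometry.axes_world()
    interp = RegularGridInterpolator((sz, sy, sx), source.grid.astype(np.float64),
                                     method="linear", bounds_error=False, fill_value=0.0)
    tz, ty, tx = GridGeometry(target.shape, target.voxel_size, target.origin).axes_world()
    Z, Y, X = np.meshgrid(tz, ty, tx, indexing="ij")
    pts = np.stack([Z.ravel(), Y.ravel(), X.ravel()], axis=1)
    values = interp(pts).reshape(target.shape)
    return DensityMap(values, np.asarray(target.voxel_size), np.asarray(target.origin),
                      identifier=source.identifier + "|resampled")


def correlate(map_a: DensityMap, map_b: DensityMap, mode: str = "about_zero",
              mask_threshold: float = 0.0) -> float:
    """Cross-correlation of two maps on identical geometry.

    The mask is the set of voxels where ``map_b`` exceeds ``mask_threshold``
    (map_b is conventionally the model-simulated map).  ``about_zero``
    returns Σab/√(Σa²Σb²); ``about_mean`` subtracts the masked means first
    (Pearson).
    """
    if mode not in ("about_zero", "about_mean"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    if not map_a.same_geometry(map_b):
        raise ValueError("maps differ in grid geometry; resample first")
    mask = map_b.grid > mask_threshold
    if not mask.any():
        raise DegenerateInputError("correlation mask is empty "
                                   f"(no voxels of map_b above {mask_threshold})")
    a = map_a.grid[mask].astype(np.float64)
    b = map_b.grid[mask].astype(np.float64)
    if mode == "about_mean":
        a = a - a.mean()
        b = b - b.mean()
        if not a.any() or not b.any():
            raise DegenerateInputError("zero variance inside the mask (about_mean mode)")
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0.0:
        raise DegenerateInputError("zero norm inside the mask")
    return float(np.clip((a @ b) / den, -1.0, 1.0))


# ---------------------------------------------------------------------------
# MRC2014 / CCP4 file I/O (gemmi-backed)

_SUPPORTED_MODES = {0, 1, 2}  # int8, int16, float32


def read_map(path) -> DensityMap:
    """Read an MRC2014/CCP4 map.

    The header's axis-order mapping (mapc/mapr/maps) is applied so the grid
    is always (z, y, x) in memory.  Voxel size comes from cella/(mx,my,mz).
    The origin is the ORIGIN header if any component is nonzero, otherwise
    nstart × voxel_size.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path.name}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapFormatError(f"{path.name}: unsupported MRC mode {mode} "
                             "(modes 0, 1, 2 are supported)")
    ccp4.setup(0.0, gemmi.MapSetup.ReorderOnly)
    nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=float)
    m_xyz = np.array([ccp4.header_i32(i) for i in (8, 9, 10)], dtype=float)
    if np.any(m_xyz <= 0):
        raise MapFormatError(f"{path.name}: invalid sampling mx/my/mz {m_xyz}")
    cell = ccp4.grid.unit_cell
    voxel = np.array([cell.a, cell.b, cell.c]) / m_xyz
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)], dtype=float)
    if not np.any(origin):
        origin = nstart * voxel
    grid = np.array(ccp4.grid.array, copy=True).transpose(2, 1, 0)
    return DensityMap(grid, voxel, origin, identifier=path.stem)


def write_map(density_map: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2 (float32) with voxel size and ORIGIN."""
    path = Path(path)
    nz, ny, nx = density_map.grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.array[...] = np.ascontiguousarray(
        density_map.grid.transpose(2, 1, 0).astype(np.float32))
    vx, vy, vz = density_map.voxel_size
    g.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), density_map.origin):
        m.set_header_float(word, float(val))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
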