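"""Density maps: synthesis from coordinates, correlation-coefficient fitting
objective, analytic per-atom fitting forces, and cloud-in-cell regridding.

A simulated map spreads each atom's mass onto the grid with a Gaussian kernel
whose width is set by the map resolution; the fitting objective is minus the
real-space correlation coefficient (CC) between simulated and experimental
maps, and the fitting force on each atom is the analytic gradient of CC
chained through the Gaussian spreading weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .structure import AtomicModel, RigidTransform

#: Kernel-width convention: sigma = resolution * RESOLUTION_SIGMA_FACTOR.
#: Chosen so the Fourier-space Gaussian falls to 1/e of its peak at spatial
#: frequency 1/resolution.  A single configurable constant: CC and force
#: correctness are insensitive to its exact value.
RESOLUTION_SIGMA_FACTOR = math.sqrt(0.5) / math.pi


@dataclass
class DensityMap:
    """Regular 3-D grid of density values.

    values[ix, iy, iz] lives at origin + (ix, iy, iz) * spacing.  Units are
    mass-density for simulated maps, arbitrary for experimental ones.
    """

    origin: np.ndarray      # (3,) A
    spacing: np.ndarray     # (3,) A / voxel
    values: np.ndarray      # (nx, ny, nz)
    resolution: float       # A

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_positions(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-center positions (A)."""
        ax = [self.axis_coords(a) for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def same_grid(self, other: "DensityMap") -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.spacing, other.spacing))

    def copy(self) -> "DensityMap":
        return replace(self, origin=self.origin.copy(),
                       spacing=self.spacing.copy(), values=self.values.copy())


@dataclass
class EMFitParams:
    """Parameters of the density-fitting force term."""

    resolution: float           # A
    n_neighbor: int = 4         # Gaussian truncated to n grid planes per side
    w_em: float = 1.0           # dimensionless force-balance weight
    k_em: float = 1.0           # energy weight multiplying -CC

    def __post_init__(self):
        if self.n_neighbor not in (3, 4):
            raise ValueError("n_neighbor must be 3 or 4")
        if self.w_em < 0:
            raise ValueError("w_em must be >= 0")


def grid_for_model(model: AtomicModel, spacing: float = 2.0,
                   margin: float = 12.0) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Convenience: an (origin, spacing, dims) grid covering `model` with a
    symmetric margin (A) on all sides."""
    lo = model.coords.min(axis=0) - margin
    hi = model.coords.max(axis=0) + margin
    sp = np.full(3, float(spacing))
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / sp[a])) + 1 for a in range(3))
    return lo, sp, dims


def _stencil_bounds(frac_idx: np.ndarray, n_neighbor: int, dims) -> tuple:
    """Per-atom inclusive index bounds of the (2n)^3 truncation stencil:
    n grid planes below and n above the atom along each axis."""
    base = np.floor(frac_idx).astype(int)
    lo = base - (n_neighbor - 1)
    hi = base + n_neighbor
    return lo, hi


def synthesize_map(model: AtomicModel, origin, spacing, dims,
                   resolution: float, n_neighbor: int = 4) -> DensityMap:
    """Simulated density: sum over atoms of mass x Gaussian kernel, truncated
    to `n_neighbor` nearest grid planes per axis in each direction.

    The kernel is the normalized 3-D Gaussian times the voxel volume, so an
    untruncated single-atom map sums to the atom's mass.
    """
    origin = np.asarray(origin, float).reshape(3)
    spacing = np.asarray(spacing, float).reshape(3)
    dims = tuple(int(d) for d in dims)
    sigma = resolution * RESOLUTION_SIGMA_FACTOR
    frac = (model.coords - origin) / spacing
    lo, hi = _stencil_bounds(frac, n_neighbor, dims)
    bad = np.flatnonzero((lo < 0).any(axis=1)
                         | (hi >= np.array(dims)).any(axis=1))
    if bad.size:
        raise ValueError(
            f"atoms outside grid margin (stencil would leave grid): "
            f"indices {bad[:10].tolist()}{'...' if bad.size > 10 else ''}")
    values = np.zeros(dims)
    norm1d = spacing / (math.sqrt(2 * math.pi) * sigma)
    for i in range(model.n_atoms):
        w = []
        for a in range(3):
            idx = np.arange(lo[i, a], hi[i, a] + 1)
            x = origin[a] + idx * spacing[a] - model.coords[i, a]
            w.append(norm1d[a] * np.exp(-x * x / (2 * sigma * sigma)))
        kern = model.masses[i] * (w[0][:, None, None]
                                  * w[1][None, :, None]
                                  * w[2][None, None, :])
        values[lo[i, 0]:hi[i, 0] + 1,
               lo[i, 1]:hi[i, 1] + 1,
               lo[i, 2]:hi[i, 2] + 1] += kern
    return DensityMap(origin=origin, spacing=spacing, values=values,
                      resolution=float(resolution))


def correlation_coefficient(sim: DensityMap, exp: DensityMap) -> float:
    """Real-space (non-centered) correlation coefficient of two maps on the
    same grid: sum(rho_sim rho_exp) / sqrt(sum rho_sim^2 sum rho_exp^2)."""
    if not sim.same_grid(exp):
        raise ValueError("maps must share the same grid")
    s = sim.values.ravel()
    e = exp.values.ravel()
    ss = float(s @ s)
    ee = float(e @ e)
    if ss == 0.0 or ee == 0.0:
        raise ValueError("CC undefined: one map is identically zero")
    return float(s @ e) / math.sqrt(ss * ee)


def clamp_negative(map_: DensityMap) -> DensityMap:
    """Elementwise max(value, 0); grid metadata unchanged."""
    out = map_.copy()
    np.maximum(out.values, 0.0, out=out.values)
    return out


def em_force(model: AtomicModel, exp: DensityMap,
             params: EMFitParams) -> np.ndarray:
    """Per-atom density-fitting force k_EM * dCC/dr_i (kcal/mol/A when k_EM
    carries those units).

    The CC gradient is taken with respect to the simulated voxel densities
    and chained to atomic positions through the Gaussian spreading weights,
    using the same truncation stencil as :func:`synthesize_map`.
    """
    sim = synthesize_map(model, exp.origin, exp.spacing, exp.dims,
                         params.resolution, params.n_neighbor)
    s = sim.values
    e = exp.values
    ss = float((s * s).sum())
    ee = float((e * e).sum())
    if ss == 0.0:
        raise ValueError("zero simulated density")
    if ee == 0.0:
        raise ValueError("zero experimental density")
    num = float((s * e).sum())
    denom = math.sqrt(ss * ee)
    # dCC/drho_sim_k
    D = (e - (num / ss) * s) / denom

    sigma = params.resolution * RESOLUTION_SIGMA_FACTOR
    frac = (model.coords - exp.origin) / exp.spacing
    lo, hi = _stencil_bounds(frac, params.n_neighbor, exp.dims)
    norm1d = exp.spacing / (math.sqrt(2 * math.pi) * sigma)
    forces = np.zeros((model.n_atoms, 3))
    for i in range(model.n_atoms):
        w, dx = [], []
        for a in range(3):
            idx = np.arange(lo[i, a], hi[i, a] + 1)
            x = exp.origin[a] + idx * exp.spacing[a] - model.coords[i, a]
            w.append(norm1d[a] * np.exp(-x * x / (2 * sigma * sigma)))
            dx.append(x)
        Dsub = D[lo[i, 0]:hi[i, 0] + 1,
                 lo[i, 1]:hi[i, 1] + 1,
                 lo[i, 2]:hi[i, 2] + 1]
        kern = model.masses[i] * (w[0][:, None, None]
                                  * w[1][None, :, None]
                                  * w[2][None, None, :])
        G = Dsub * kern
        # d kernel / d r_i,a = kernel * (V_a - r_a) / sigma^2
        forces[i, 0] = (G * (dx[0][:, None, None] / sigma ** 2)).sum()
        forces[i, 1] = (G * (dx[1][None, :, None] / sigma ** 2)).sum()
        forces[i, 2] = (G * (dx[2][None, None, :] / sigma ** 2)).sum()
    return params.k_em * forces


def scale_weight(em_forces: np.ndarray, str_forces: np.ndarray,
                 w_em: float) -> float:
    """Energy weight k_EM making the mean atomic EM-force magnitude equal
    w_EM times the mean structural-force magnitude."""
    em_forces = np.asarray(em_forces, float).reshape(-1, 3)
    str_forces = np.asarray(str_forces, float).reshape(-1, 3)
    if em_forces.size == 0 or str_forces.size == 0:
        raise ValueError("force sets must be non-empty")
    mean_em = np.linalg.norm(em_forces, axis=1).mean()
    mean_str = np.linalg.norm(str_forces, axis=1).mean()
    if mean_em == 0.0:
        raise ValueError("all EM forces are zero; cannot scale")
    if mean_str <= 0.0:
        raise ValueError("mean structural force must be positive")
    return w_em * mean_str / mean_em


def cic_regrid(map_: DensityMap, transform: RigidTransform,
               origin, spacing, dims,
               clip_tolerance: float = 1e-9) -> DensityMap:
    """Cloud-in-cell regridding: each source voxel's value, placed at its
    transformed position, is shared among the 8 surrounding target voxels
    with trilinear weights.  Total density is conserved.
    """
    origin = np.asarray(origin, float).reshape(3)
    spacing = np.asarray(spacing, float).reshape(3)
    dims = tuple(int(d) for d in dims)
    src_pos = map_.voxel_positions()
    vals = map_.values.ravel()
    nz = vals != 0
    src_pos = src_pos[nz]
    vals = vals[nz]
    q = transform.apply(src_pos)
    f = (q - origin) / spacing
    i0 = np.floor(f).astype(int)
    frac = f - i0
    out = np.zeros(dims)
    clipped = 0.0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        ok = ((idx >= 0) & (idx < np.array(dims))).all(axis=1)
        clipped += float((w[~ok] * vals[~ok]).sum())
        np.add.at(out, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), w[ok] * vals[ok])
    total = float(np.abs(vals).sum())
    if total > 0 and abs(clipped) > clip_tolerance * total:
        raise ValueError(
            f"transformed support exceeds target grid: clipped mass "
            f"{clipped:.6g} of total {total:.6g}")
    return DensityMap(origin=origin, spacing=spacing, values=out,
                      resolution=map_.resolution)


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O (gemmi-backed; MRC2014, MODE 2, X-fastest on read)
# ---------------------------------------------------------------------------

def write_mrc(map_: DensityMap, path) -> None:
    m = gemmi.Ccp4Map()
    nx, ny, nz = map_.dims
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(map_.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(nx * map_.spacing[0],
                                      ny * map_.spacing[1],
                                      nz * map_.spacing[2],
                                      90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2)
    m.set_header_float(50, float(map_.origin[0]))
    m.set_header_float(51, float(map_.origin[1]))
    m.set_header_float(52, float(map_.origin[2]))
    m.write_ccp4_map(str(path))


def read_mrc(path, resolution: float = 0.0) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))  # normalize to X-fastest full cell
    values = np.array(m.grid, copy=True)
    nx, ny, nz = values.shape
    cell = m.grid.unit_cell
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)])
    values = np.nan_to_num(values, nan=0.0)
    return DensityMap(origin=origin, spacing=spacing,
                      values=values.astype(float), resolution=resolution)
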