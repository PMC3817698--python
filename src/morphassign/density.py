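"""Density maps: I/O, rasterisation of atomic models, interpolation and
local map-model correlation statistics.

A map is a 3-D array of values on an orthogonal grid with per-axis spacing
and an Å origin.  Model density is computed as a sum of isotropic atomic
Gaussians whose integrated weight is the atom's electron count (times
occupancy) and whose width combines the atomic B factor with an extra blur
term that sets the effective resolution of the synthetic maps (~3 Å for the
default blur of 50 Å²).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import (EmptyModelError, MorphAssignError, OutOfBoundsError,
                     UnsupportedFormatError)
from .structure_io import AtomicModel

__all__ = [
    "DensityMap", "ResidueDensityStats", "read_map", "write_map",
    "rasterize", "interpolate", "local_correlation", "residue_stats",
]

GAUSSIAN_CUTOFF_SIGMA = 4.5      # truncation radius of the atomic Gaussian
DEFAULT_BLUR_B = 50.0            # Å²; ~3 Å effective resolution
DEFAULT_CC_RADIUS = 2.5          # Å; sphere for per-residue correlation


@dataclass
class DensityMap:
    values: np.ndarray            # (nx, ny, nz)
    spacing: np.ndarray           # (3,) Å per grid step
    origin: np.ndarray            # (3,) Å position of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=float) * np.ones(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with extent >= 2 per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")

    @property
    def extent(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        """Å position of the last grid node along each axis."""
        return self.origin + (np.array(self.values.shape) - 1) * self.spacing

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.spacing.copy(),
                          self.origin.copy())

    def frac_coords(self, points: np.ndarray) -> np.ndarray:
        """Continuous grid coordinates of Å points (no bounds check)."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.all((pts >= self.origin + margin) &
                      (pts <= self.upper - margin), axis=1)

    def grid_points_in_sphere(self, center: np.ndarray, radius: float
                              ) -> tuple[np.ndarray, np.ndarray]:
        """Grid nodes within ``radius`` Å of ``center``.

        Returns (index array (n,3), Å positions (n,3)).
        """
        center = np.asarray(center, float)
        lo = np.maximum(np.ceil((center - radius - self.origin) / self.spacing),
                        0).astype(int)
        hi = np.minimum(np.floor((center + radius - self.origin) / self.spacing),
                        np.array(self.values.shape) - 1).astype(int)
        if np.any(hi < lo):
            return np.empty((0, 3), int), np.empty((0, 3))
        axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        pos = self.origin + idx * self.spacing
        keep = np.linalg.norm(pos - center, axis=1) <= radius
        return idx[keep], pos[keep]


# --------------------------------------------------------------------------
# CCP4/MRC I/O (orthogonal cells only)
# --------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map with an orthogonal (90,90,90) cell."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise UnsupportedFormatError(
            f"non-orthogonal map cell ({cell.alpha}, {cell.beta}, {cell.gamma});"
            " only 90,90,90 cells are supported")
    values = np.array(m.grid.array, dtype=np.float64)
    nx, ny, nz = values.shape
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    return DensityMap(values, spacing, origin)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    nx, ny, nz = dmap.values.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * dmap.spacing[0],
                                      ny * dmap.spacing[1],
                                      nz * dmap.spacing[2], 90, 90, 90))
    grid.array[:] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(i, float(v))
    m.write_ccp4_map(str(path))


# --------------------------------------------------------------------------
# Rasterisation and interpolation
# --------------------------------------------------------------------------

def b_to_sigma(b_total: float) -> float:
    """Gaussian width (Å) of an atom with total B ``b_total`` Å²."""
    return float(np.sqrt(b_total / (8.0 * np.pi ** 2)))


def _add_gaussian(values: np.ndarray, origin: np.ndarray, spacing: np.ndarray,
                  pos: np.ndarray, weight: float, sigma: float) -> None:
    cutoff = GAUSSIAN_CUTOFF_SIGMA * sigma
    lo = np.maximum(np.ceil((pos - cutoff - origin) / spacing), 0).astype(int)
    hi = np.minimum(np.floor((pos + cutoff - origin) / spacing),
                    np.array(values.shape) - 1).astype(int)
    if np.any(hi < lo):
        return
    ax = [origin[d] + spacing[d] * np.arange(lo[d], hi[d] + 1) - pos[d]
          for d in range(3)]
    r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    amp = weight / ((2 * np.pi * sigma * sigma) ** 1.5)
    g = amp * np.exp(-r2 / (2 * sigma * sigma))
    g[r2 > cutoff * cutoff] = 0.0
    values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += g


def rasterize(model: AtomicModel, like: DensityMap | None = None, *,
              origin: np.ndarray | None = None,
              spacing: float | np.ndarray | None = None,
              shape: tuple[int, int, int] | None = None,
              blur_b: float = DEFAULT_BLUR_B,
              check_bounds: bool = True) -> DensityMap:
    """Compute model density on a grid as a sum of atomic Gaussians.

    The grid geometry is taken from ``like`` or given explicitly.  Each atom
    contributes an isotropic Gaussian of integrated weight electrons x
    occupancy and variance (B_atom + blur_b)/(8 pi^2), truncated at 4.5 sigma.
    """
    if like is not None:
        origin, spacing, shape = like.origin, like.spacing, like.values.shape
    if origin is None or spacing is None or shape is None:
        raise ValueError("grid geometry required (pass `like` or explicit args)")
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float) * np.ones(3)
    values = np.zeros(shape, dtype=np.float64)
    upper = origin + (np.array(shape) - 1) * spacing
    n_atoms = 0
    for atom in model.atoms():
        if check_bounds and (np.any(atom.pos < origin) or np.any(atom.pos > upper)):
            raise OutOfBoundsError(
                f"atom {atom.name} at {atom.pos} outside grid "
                f"[{origin}, {upper}]")
        sigma = b_to_sigma(atom.b + blur_b)
        _add_gaussian(values, origin, spacing, atom.pos, atom.electrons, sigma)
        n_atoms += 1
    if n_atoms == 0:
        raise EmptyModelError("cannot rasterize a model with no atoms")
    return DensityMap(values, spacing, origin)


def interpolate(dmap: DensityMap, points: np.ndarray) -> np.ndarray | float:
    """Trilinear interpolation of the map at Å point(s).

    Exact at grid nodes; raises OutOfBoundsError for points outside the
    grid bounding box.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(dmap.contains(pts)):
        bad = pts[~dmap.contains(pts)][0]
        raise OutOfBoundsError(f"point {bad} outside map bounds "
                               f"[{dmap.origin}, {dmap.upper}]")
    f = dmap.frac_coords(pts)
    nmax = np.array(dmap.values.shape) - 1
    i0 = np.minimum(np.floor(f).astype(int), nmax - 1)
    t = f - i0
    v = dmap.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    c = (v[ix, iy, iz] * (1 - tx) * (1 - ty) * (1 - tz)
         + v[ix + 1, iy, iz] * tx * (1 - ty) * (1 - tz)
         + v[ix, iy + 1, iz] * (1 - tx) * ty * (1 - tz)
         + v[ix, iy, iz + 1] * (1 - tx) * (1 - ty) * tz
         + v[ix + 1, iy + 1, iz] * tx * ty * (1 - tz)
         + v[ix + 1, iy, iz + 1] * tx * (1 - ty) * tz
         + v[ix, iy + 1, iz + 1] * (1 - tx) * ty * tz
         + v[ix + 1, iy + 1, iz + 1] * tx * ty * tz)
    if np.ndim(points) == 1:
        return float(c[0])
    return c


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either side has zero variance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.sum(da * db) / (na * nb), -1.0, 1.0))


def local_correlation(dmap: DensityMap, model_density: DensityMap,
                      center: np.ndarray, radius: float) -> float:
    """Pearson correlation of map and model density over a sphere of grid
    points of ``dmap`` centred at ``center``."""
    _, pos = dmap.grid_points_in_sphere(center, radius)
    if len(pos) < 2:
        raise MorphAssignError(
            f"fewer than two grid points within {radius} Å of {center}; "
            "radius below grid spacing?")
    a = interpolate(dmap, pos)
    b = interpolate(model_density, pos)
    return pearson(a, b)


# --------------------------------------------------------------------------
# Per-residue statistics
# --------------------------------------------------------------------------

@dataclass
class ResidueDensityStats:
    """Per-residue density statistics of a model against a map.

    ``rho_mean[i]`` is the mean map value at the atom positions of residue i
    (in model iteration order); ``rho_mean_all``/``sd_mean_all`` are the mean
    and (population) SD of those per-residue values; ``cc[i]`` is the local
    map-model correlation in a sphere at the residue centroid.
    """
    keys: list[tuple[str, int]]
    rho_mean: np.ndarray
    cc: np.ndarray
    rho_mean_all: float
    sd_mean_all: float

    def as_dict(self) -> dict[tuple[str, int], tuple[float, float]]:
        return {k: (float(r), float(c))
                for k, r, c in zip(self.keys, self.rho_mean, self.cc)}


def residue_stats(dmap: DensityMap, model: AtomicModel, *,
                  model_density: DensityMap | None = None,
                  blur_b: float = DEFAULT_BLUR_B,
                  cc_radius: float = DEFAULT_CC_RADIUS) -> ResidueDensityStats:
    """Compute rho_mean per residue and local correlations.

    ``model_density`` may be passed to reuse an existing rasterisation;
    otherwise the model is rasterised on the map grid with ``blur_b``.
    """
    if model.n_residues == 0:
        raise EmptyModelError("residue_stats on empty model")
    if model_density is None:
        model_density = rasterize(model, like=dmap, blur_b=blur_b)
    keys: list[tuple[str, int]] = []
    rho: list[float] = []
    ccs: list[float] = []
    for ch, res in model.residues():
        pts = np.array([a.pos for a in res.atoms])
        rho.append(float(np.mean(interpolate(dmap, pts))))
        ccs.append(local_correlation(dmap, model_density, res.centroid(),
                                     cc_radius))
        keys.append((ch.id, res.seqid))
    rho_arr = np.array(rho)
    return ResidueDensityStats(
        keys=keys, rho_mean=rho_arr, cc=np.array(ccs),
        rho_mean_all=float(rho_arr.mean()),
        sd_mean_all=float(rho_arr.std()))
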