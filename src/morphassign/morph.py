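"""Real-space model morphing.

Morphing smoothly deforms a placed model to better fit a density map while
leaving the residues themselves untouched.  Each cycle:

1. for every residue, find the small rigid translation of the model density
   of its 6 Å neighbourhood that maximises the local correlation with the
   map (discrete lattice search inside a capped ball, then one half-step
   polish);
2. smooth the per-residue shift vectors with a boxcar window along the
   chain, never crossing chain breaks;
3. translate all atoms of each residue by its smoothed shift (intra-residue
   geometry is exactly preserved);
4. regularise the geometry of the connecting peptide links with a
   restrained real-space minimisation.

Six cycles are run by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import minimize

from . import constants as C
from ._kernels import shift_correlations
from .density import DEFAULT_BLUR_B, DensityMap, b_to_sigma, rasterize, residue_stats
from .errors import MorphAssignError
from .structure_io import AtomicModel, Chain, Residue, contiguous_runs

logger = logging.getLogger(__name__)

__all__ = [
    "MorphConfig", "ShiftField", "shift_candidates", "local_shift",
    "smooth_shifts", "apply_shifts", "regularize", "morph",
]


class MorphConfig(BaseModel):
    """Parameters of the morphing procedure.

    Defaults: correlation neighbourhood of 6 Å around each CA, translations
    capped at 2 Å, shifts smoothed over a 10-residue window, six cycles.
    """
    sphere_radius: float = Field(6.0, gt=0)
    max_shift: float = Field(2.0, gt=0)
    smooth_window: int = Field(10, ge=1)
    n_cycles: int = Field(6, ge=0)
    shift_search_step: float = Field(0.25, gt=0)
    local_grid_spacing: float = Field(0.5, gt=0)
    blur_b: float = Field(DEFAULT_BLUR_B, ge=0)
    w_tether: float = Field(10.0, gt=0)
    regularize_each_cycle: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.shift_search_step > self.max_shift:
            raise ValueError("shift_search_step must not exceed max_shift")
        return self

    @property
    def effective_window(self) -> int:
        """Smoothing window rounded up to an odd number of residues."""
        w = self.smooth_window
        return w if w % 2 == 1 else w + 1


@dataclass
class ShiftField:
    """One 3-vector per residue, keyed by (chain id, residue number).

    ``None`` marks residues for which no raw shift could be measured (e.g.
    no CA); smoothing fills these from their neighbours.
    """
    shifts: dict[tuple[str, int], np.ndarray | None] = field(default_factory=dict)
    smoothed: bool = False
    window: int | None = None

    def norms(self) -> np.ndarray:
        vs = [v for v in self.shifts.values() if v is not None]
        return np.array([np.linalg.norm(v) for v in vs]) if vs else np.zeros(0)


def shift_candidates(max_shift: float, step: float) -> np.ndarray:
    """Lattice of candidate translations inside the ball |t| <= max_shift,
    ordered by (norm, x, y, z) so the first argmax wins ties."""
    n = int(np.floor(max_shift / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    cand = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    cand = cand[np.linalg.norm(cand, axis=1) <= max_shift + 1e-9]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                        np.linalg.norm(cand, axis=1)))
    return cand[order]


def _neighbourhood(model: AtomicModel, center: np.ndarray, radius: float):
    pos, wt, bs = [], [], []
    for atom in model.atoms():
        if np.linalg.norm(atom.pos - center) <= radius:
            pos.append(atom.pos)
            wt.append(atom.electrons)
            bs.append(atom.b)
    return np.array(pos), np.array(wt), np.array(bs)


def _local_model_grid(center: np.ndarray, pos: np.ndarray, wt: np.ndarray,
                      bs: np.ndarray, cfg: MorphConfig) -> DensityMap:
    """Rasterise the neighbourhood atoms on a local fine grid that covers
    every point the shift search will sample."""
    reach = cfg.sphere_radius + cfg.max_shift + cfg.shift_search_step + 1.0
    lo = center - reach
    h = cfg.local_grid_spacing
    shape = tuple(int(np.ceil(2 * reach / h)) + 1 for _ in range(3))
    values = np.zeros(shape)
    from .density import _add_gaussian  # local import to avoid cycle noise
    spacing = np.full(3, h)
    for p, w, b in zip(pos, wt, bs):
        _add_gaussian(values, lo, spacing, p, w, b_to_sigma(b + cfg.blur_b))
    return DensityMap(values, spacing, lo)


def correlation_at_shifts(dmap: DensityMap, local_density: DensityMap,
                          sphere_pts: np.ndarray, map_vals: np.ndarray,
                          shifts: np.ndarray) -> np.ndarray:
    """Correlations between the map samples and the translated local model
    density for each candidate shift (thin wrapper over the search kernel)."""
    return shift_correlations(
        np.ascontiguousarray(map_vals, dtype=np.float64),
        np.ascontiguousarray(local_density.values, dtype=np.float64),
        np.ascontiguousarray(local_density.origin, dtype=np.float64),
        np.ascontiguousarray(local_density.spacing, dtype=np.float64),
        np.ascontiguousarray(sphere_pts, dtype=np.float64),
        np.ascontiguousarray(shifts, dtype=np.float64))


def _best(cand: np.ndarray, corr: np.ndarray) -> np.ndarray:
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                        np.linalg.norm(cand, axis=1), -corr))
    return cand[order[0]]


def local_shift(dmap: DensityMap, model: AtomicModel, residue: Residue,
                cfg: MorphConfig, polish: bool = True) -> np.ndarray:
    """Translation (Å) of the residue's 6 Å model-density neighbourhood that
    maximises local correlation with the map.

    Discrete search on a lattice of step ``shift_search_step`` inside the
    ball of radius ``max_shift``, optionally followed by one half-step local
    polish.  Ties break towards the smallest shift norm, then
    lexicographically.  Returns the zero vector (with a warning) when no
    atoms or too few map points are available.
    """
    ca = residue.ca
    if ca is None:
        raise MorphAssignError(f"residue {residue.seqid} has no CA")
    pos, wt, bs = _neighbourhood(model, ca.pos, cfg.sphere_radius)
    if len(pos) == 0:
        logger.warning("no atoms within %.1f Å of residue %s; zero shift",
                       cfg.sphere_radius, residue.seqid)
        return np.zeros(3)
    idx, pts = dmap.grid_points_in_sphere(ca.pos, cfg.sphere_radius)
    inside = dmap.contains(pts)
    idx, pts = idx[inside], pts[inside]
    if len(pts) < 8:
        logger.warning("residue %s sphere outside map; zero shift",
                       residue.seqid)
        return np.zeros(3)
    map_vals = dmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    local = _local_model_grid(ca.pos, pos, wt, bs, cfg)
    cand = shift_candidates(cfg.max_shift, cfg.shift_search_step)
    corr = correlation_at_shifts(dmap, local, pts, map_vals, cand)
    best = _best(cand, corr)
    if polish:
        half = cfg.shift_search_step / 2.0
        ax = np.array([-half, 0.0, half])
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        extra = best + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        extra = extra[np.linalg.norm(extra, axis=1) <= cfg.max_shift + 1e-9]
        if len(extra):
            corr2 = correlation_at_shifts(dmap, local, pts, map_vals, extra)
            best = _best(extra, corr2)
    return best


def compute_raw_shifts(dmap: DensityMap, model: AtomicModel,
                       cfg: MorphConfig) -> ShiftField:
    """Raw (unsmoothed) shift field over all residues of the model."""
    fld = ShiftField()
    for ch, res in model.residues():
        if res.ca is None:
            fld.shifts[(ch.id, res.seqid)] = None
        else:
            fld.shifts[(ch.id, res.seqid)] = local_shift(dmap, model, res, cfg)
    return fld


def smooth_shifts(raw: ShiftField, window: int,
                  model: AtomicModel) -> ShiftField:
    """Boxcar-average the raw shifts along each chain.

    The window is truncated at chain ends and never crosses a chain break
    (numbering gap or CA-CA jump).  Residues without a raw shift receive
    the average of the available shifts in their window.
    """
    w = window if window % 2 == 1 else window + 1
    half = w // 2
    out = ShiftField(smoothed=True, window=w)
    for ch in model.chains:
        for run in contiguous_runs(ch):
            keys = [(ch.id, r.seqid) for r in run]
            vecs = [raw.shifts.get(k) for k in keys]
            for i, k in enumerate(keys):
                lo = max(0, i - half)
                hi = min(len(keys), i + half + 1)
                vs = [v for v in vecs[lo:hi] if v is not None]
                out.shifts[k] = (np.mean(vs, axis=0) if vs else np.zeros(3))
    return out


def apply_shifts(model: AtomicModel, shifts: ShiftField) -> AtomicModel:
    """Translate every atom of each residue by the residue's shift."""
    out = model.copy()
    for ch, res in out.residues():
        key = (ch.id, res.seqid)
        if key not in shifts.shifts or shifts.shifts[key] is None:
            raise MorphAssignError(f"no shift for residue {key}")
        res.translate(shifts.shifts[key])
    return out


# --------------------------------------------------------------------------
# Geometry regularisation
# --------------------------------------------------------------------------

_LINK_RESTRAINTS = [
    ("C", "N", C.BOND_C_N, 100.0),
    ("CA", "N", C.DIST_CA_N_NEXT, 30.0),
    ("C", "CA", C.DIST_C_CA_NEXT, 30.0),
    ("O", "N", C.DIST_O_N_NEXT, 30.0),
    ("CA", "CA", C.DIST_CA_CA_TRANS, 10.0),
]
_W_INTRA = 100.0
_LINK_SKIP_CN = 3.0   # Å; links already stretched beyond this are real gaps


def _collect_restraints(model: AtomicModel):
    """Index atoms and build (i, j, d0, w) distance restraints."""
    atoms: list = []
    index: dict[int, int] = {}
    for _, res in model.residues():
        for a in res.atoms:
            index[id(a)] = len(atoms)
            atoms.append(a)
    pairs: list[tuple[int, int, float, float]] = []
    for ch in model.chains:
        for res in ch.residues:
            # intra-residue: preserve the input geometry rigidly
            n = len(res.atoms)
            for i in range(n):
                for j in range(i + 1, n):
                    d0 = float(np.linalg.norm(res.atoms[i].pos - res.atoms[j].pos))
                    if d0 > 1e-6:
                        pairs.append((index[id(res.atoms[i])],
                                      index[id(res.atoms[j])], d0, _W_INTRA))
        for prev, nxt in zip(ch.residues, ch.residues[1:]):
            if nxt.seqid != prev.seqid + 1:
                continue
            c, nn = prev.atom("C"), nxt.atom("N")
            if c is None or nn is None:
                continue
            if np.linalg.norm(c.pos - nn.pos) > _LINK_SKIP_CN:
                continue  # deletion gap, not a broken link to repair
            for an1, an2, d0, w in _LINK_RESTRAINTS:
                a1, a2 = prev.atom(an1), nxt.atom(an2)
                if a1 is not None and a2 is not None:
                    pairs.append((index[id(a1)], index[id(a2)], d0, w))
    return atoms, pairs


def regularize(model: AtomicModel, w_tether: float = 10.0,
               max_iter: int = 300, max_move: float = 1.5) -> AtomicModel:
    """Restore ideal peptide-link geometry by restrained minimisation.

    Minimises a sum of harmonic distance restraints (intra-residue
    distances at their input values, inter-residue link distances at ideal
    values) plus harmonic tethers of weight ``w_tether`` to the input
    coordinates.  No atom moves more than ``max_move`` Å.
    """
    out = model.copy()
    atoms, pairs = _collect_restraints(out)
    if not pairs:
        return out
    x0 = np.array([a.pos for a in atoms])
    n = len(atoms)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    d0 = np.array([p[2] for p in pairs])
    ww = np.array([p[3] for p in pairs])

    def fun(x_flat: np.ndarray):
        x = x_flat.reshape(n, 3)
        dv = x[ii] - x[jj]
        d = np.linalg.norm(dv, axis=1)
        d_safe = np.maximum(d, 1e-9)
        err = d - d0
        e = np.sum(ww * err * err)
        g = np.zeros_like(x)
        coef = (2.0 * ww * err / d_safe)[:, None] * dv
        np.add.at(g, ii, coef)
        np.add.at(g, jj, -coef)
        dt = x - x0
        e += w_tether * np.sum(dt * dt)
        g += 2.0 * w_tether * dt
        return e, g.ravel()

    res = minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    if not res.success:
        logger.warning("regularisation did not fully converge: %s",
                       res.message)
    x = res.x.reshape(n, 3)
    disp = x - x0
    norms = np.linalg.norm(disp, axis=1)
    over = norms > max_move
    if np.any(over):
        disp[over] *= (max_move / norms[over])[:, None]
        x = x0 + disp
    for a, p in zip(atoms, x):
        a.pos = p
    return out


def morph(model: AtomicModel, dmap: DensityMap,
          cfg: MorphConfig | None = None
          ) -> tuple[AtomicModel, list[dict]]:
    """Run the full morphing procedure.

    Each cycle measures per-residue shifts, smooths and applies them and
    regularises geometry.  Returns the morphed model and per-cycle
    diagnostics (mean applied shift, mean per-residue local correlation).
    """
    cfg = cfg or MorphConfig()
    work = model.copy()
    diagnostics: list[dict] = []
    for cycle in range(cfg.n_cycles):
        raw = compute_raw_shifts(dmap, work, cfg)
        smoothed = smooth_shifts(raw, cfg.effective_window, work)
        work = apply_shifts(work, smoothed)
        if cfg.regularize_each_cycle:
            work = regularize(work, w_tether=cfg.w_tether)
        stats = residue_stats(dmap, work, blur_b=cfg.blur_b)
        diagnostics.append({
            "cycle": cycle + 1,
            "mean_shift": float(np.mean(smoothed.norms())) if len(
                smoothed.norms()) else 0.0,
            "mean_cc": float(stats.cc.mean()),
        })
        logger.info("morph cycle %d: mean |shift| %.3f Å, mean CC %.3f",
                    cycle + 1, diagnostics[-1]["mean_shift"],
                    diagnostics[-1]["mean_cc"])
    return work, diagnostics
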