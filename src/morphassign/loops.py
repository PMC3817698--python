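"""Loop building between segment ends and the assignment iteration driver.

Loops are attempted only where they are plausibly needed: between segment
ends that are spatially close and between segments whose assigned sequence
spans are separated by a few residues.  A candidate loop is a CA trace
closed between the two anchor CAs by randomised piecewise-linear paths
that are alternately projected onto local density maxima and onto the
3.6-4.0 Å CA-step manifold; the densest valid trace is kept and accepted
when its mean density clears a fraction of the model's global mean
density.  Accepted loops feed the loop-bonus score term, and loops
consistent with the winning assignment are merged into the model as
backbone, creating longer segments for the next assignment round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field

from .constants import AA1_TO_3
from .assign import (AssignmentState, Constraints, PlacementMatrix,
                     ScoreConfig, Segment, apply_assignment,
                     build_placement_matrix, connection_feasible,
                     extract_segments, optimize)
from .density import DensityMap, interpolate, rasterize, residue_stats
from .structure_io import (Atom, AtomicModel, Chain, Residue, TargetSequence)

logger = logging.getLogger(__name__)

__all__ = [
    "LoopConfig", "LoopCandidate", "propose_loop_pairs", "build_loop",
    "merge_with_loops", "iterate_assignment",
]

CA_STEP_MIN = 3.6
CA_STEP_MAX = 4.0
CA_SKIP_MIN = 5.0        # minimum CA(i)-CA(i+2) distance (max ~97° bend)
_DP_STEP_LO = 3.2        # relaxed bounds on the 1 Å search lattice
_DP_STEP_HI = 4.4


class LoopConfig(BaseModel):
    """Loop proposal/closure parameters."""
    d_close: float = Field(15.0, gt=0)     # Å: "ends close together"
    g_close: int = Field(6, ge=0)          # residues: "a few residues" apart
    n_trials: int = Field(32, ge=1)        # random closure attempts
    f_loop: float = Field(0.5, ge=0)       # acceptance: mean density >= f*rho_all
    max_project_iter: int = Field(100, ge=1)
    max_extra_residues: int = Field(3, ge=0)  # lengths tried above the minimum
    trace_beam: int = Field(1500, ge=1)    # beam width of the lattice search
    max_layer_candidates: int = Field(2500, ge=10)


@dataclass
class LoopCandidate:
    """A CA-trace loop between two anchors."""
    seg_a: int
    seg_b: int
    n_res: int
    anchor_a: np.ndarray
    anchor_b: np.ndarray
    trace: np.ndarray            # (n_res, 3) interior CA positions
    mean_density: float
    accepted: bool
    reason: str = ""

    def full_path(self) -> np.ndarray:
        return np.vstack([self.anchor_a[None, :], self.trace,
                          self.anchor_b[None, :]])


def propose_loop_pairs(segments: list[Segment],
                       state: AssignmentState | None,
                       cfg: LoopConfig | None = None
                       ) -> list[tuple[int, int, int | None]]:
    """Ordered (seg_a, seg_b, gap) pairs worth attempting a loop for.

    A pair qualifies when the C-end of A is within ``d_close`` Å of the
    N-end of B, or when both are assigned with a sequence gap of at most
    ``g_close`` residues (then the gap is returned; otherwise None).
    """
    cfg = cfg or LoopConfig()
    assignment = state.assignment if state else {}
    segs = {s.index: s for s in segments}
    out: list[tuple[int, int, int | None]] = []
    for a in segments:
        for b in segments:
            if a.index == b.index:
                continue
            gap = None
            if a.index in assignment and b.index in assignment:
                g = assignment[b.index] - (assignment[a.index] + a.n)
                if 0 <= g <= cfg.g_close:
                    gap = g
            close = np.linalg.norm(a.c_end - b.n_end) <= cfg.d_close
            if close or gap is not None:
                out.append((a.index, b.index, gap))
    out.sort(key=lambda t: (t[0], t[1]))
    # deduplicate, preferring entries with a known gap
    best: dict[tuple[int, int], int | None] = {}
    for sa, sb, g in out:
        if (sa, sb) not in best or best[(sa, sb)] is None:
            best[(sa, sb)] = g
    return [(sa, sb, g) for (sa, sb), g in sorted(best.items())]


def _pair_project(path: np.ndarray, i: int, j: int, target: float) -> None:
    d = np.linalg.norm(path[j] - path[i])
    if d < 1e-9:
        return
    corr = (target - d) * (path[j] - path[i]) / d
    movable_i = 0 < i < len(path) - 1
    movable_j = 0 < j < len(path) - 1
    if movable_i and movable_j:
        path[i] -= 0.5 * corr
        path[j] += 0.5 * corr
    elif movable_j:
        path[j] += corr
    elif movable_i:
        path[i] -= corr


def _project_steps(path: np.ndarray, max_iter: int) -> bool:
    """Iteratively enforce CA steps in [3.6, 4.0] Å (and second-neighbour
    separation of at least 5.0 Å, i.e. no re-entrant bends) with fixed
    endpoints.  Returns True when converged."""
    n = len(path)
    worst = np.inf
    for _ in range(max_iter):
        worst = 0.0
        for i in range(n - 1):
            d = np.linalg.norm(path[i + 1] - path[i])
            target = min(max(d, CA_STEP_MIN), CA_STEP_MAX)
            err = abs(d - target)
            worst = max(worst, err)
            if err >= 1e-4:
                _pair_project(path, i, i + 1, target)
        for i in range(n - 2):
            d = np.linalg.norm(path[i + 2] - path[i])
            if d < CA_SKIP_MIN - 1e-4:
                worst = max(worst, CA_SKIP_MIN - d)
                _pair_project(path, i, i + 2, CA_SKIP_MIN)
        if worst < 1e-3:
            return True
    return worst < 0.05


_DENSITY_OFFSETS = None


def _density_offsets() -> np.ndarray:
    global _DENSITY_OFFSETS
    if _DENSITY_OFFSETS is None:
        ax = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        _DENSITY_OFFSETS = pts[np.linalg.norm(pts, axis=1) <= 1.0 + 1e-9]
    return _DENSITY_OFFSETS


def _project_density(path: np.ndarray, dmap: DensityMap,
                     radius: float = 1.0) -> None:
    """Pull each interior point towards the local density within ``radius``.

    The new position is the density-weighted centroid of the surrounding
    ball (weights squared to sharpen), which follows ridges smoothly
    instead of jumping to isolated maxima."""
    offs = _density_offsets() * radius
    for i in range(1, len(path) - 1):
        cand = path[i] + offs
        ok = dmap.contains(cand)
        if not np.any(ok):
            continue
        vals = np.maximum(np.asarray(interpolate(dmap, cand[ok])), 0.0) ** 2
        total = vals.sum()
        if total <= 0:
            continue
        path[i] = (vals[:, None] * cand[ok]).sum(axis=0) / total


def _densest_lattice_path(guide: DensityMap, a: np.ndarray, b: np.ndarray,
                          n_res: int, cfg: LoopConfig) -> np.ndarray | None:
    """Deterministic densest CA path on the map lattice.

    Beam dynamic programming over (previous, current) point pairs: steps
    are confined to [3.2, 4.4] Å (relaxed for the 1 Å lattice) and second
    neighbours must be >= 5 Å apart, which forbids the re-entrant paths
    that oscillate across one strong blob.  Returns the interior trace or
    None when no lattice path exists.
    """
    layers: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(1, n_res + 1):
        r_a, r_b = _DP_STEP_HI * j, _DP_STEP_HI * (n_res + 1 - j)
        lo = np.maximum(np.maximum(a - r_a, b - r_b), guide.origin)
        hi = np.minimum(np.minimum(a + r_a, b + r_b), guide.upper)
        if np.any(hi < lo):
            return None
        axes = [np.arange(int(np.ceil((lo[d] - guide.origin[d])
                                      / guide.spacing[d])),
                          int(np.floor((hi[d] - guide.origin[d])
                                       / guide.spacing[d])) + 1)
                for d in range(3)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        pos = guide.origin + idx * guide.spacing
        d_a = np.linalg.norm(pos - a, axis=1)
        d_b = np.linalg.norm(pos - b, axis=1)
        keep = (d_a <= r_a) & (d_b <= r_b)
        pos, idx = pos[keep], idx[keep]
        if len(pos) == 0:
            return None
        dens = guide.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        if len(pos) > cfg.max_layer_candidates:
            top = np.argpartition(-dens, cfg.max_layer_candidates)[
                :cfg.max_layer_candidates]
            pos, dens = pos[top], dens[top]
        layers.append((pos, dens))

    pos1, den1 = layers[0]
    d = np.linalg.norm(pos1 - a, axis=1)
    ok = (d >= _DP_STEP_LO) & (d <= _DP_STEP_HI)
    if n_res == 1:
        d_b = np.linalg.norm(pos1 - b, axis=1)
        ok &= (d_b >= _DP_STEP_LO) & (d_b <= _DP_STEP_HI)
        if not ok.any():
            return None
        return pos1[int(np.argmax(np.where(ok, den1, -np.inf)))][None, :]
    if not ok.any():
        return None
    st_prev = np.tile(a, (int(ok.sum()), 1))
    st_cur = pos1[ok]
    st_score = den1[ok].astype(float)
    st_hist: list[list[np.ndarray]] = [[p] for p in st_cur]
    for j in range(1, n_res):
        pos, dens = layers[j]
        dc = np.linalg.norm(pos[None, :, :] - st_cur[:, None, :], axis=2)
        dp = np.linalg.norm(pos[None, :, :] - st_prev[:, None, :], axis=2)
        okm = (dc >= _DP_STEP_LO) & (dc <= _DP_STEP_HI) & (dp >= CA_SKIP_MIN)
        sc = np.where(okm, st_score[:, None] + dens[None, :], -np.inf)
        flat = sc.ravel()
        n_valid = int(np.isfinite(flat).sum())
        if n_valid == 0:
            return None
        k = min(cfg.trace_beam, n_valid)
        top = np.argpartition(-flat, k - 1)[:k]
        si, ci = np.unravel_index(top, sc.shape)
        st_hist = [st_hist[s] + [pos[c]] for s, c in zip(si, ci)]
        st_prev = st_cur[si]
        st_cur = pos[ci]
        st_score = flat[top]
    d_b = np.linalg.norm(st_cur - b, axis=1)
    dp_b = np.linalg.norm(st_prev - b, axis=1)
    ok = (d_b >= _DP_STEP_LO) & (d_b <= _DP_STEP_HI) & (dp_b >= CA_SKIP_MIN)
    if not ok.any():
        return None
    best = int(np.argmax(np.where(ok, st_score, -np.inf)))
    return np.array(st_hist[best])


def build_loop(anchor_a: np.ndarray, anchor_b: np.ndarray, n_res: int,
               dmap: DensityMap, rho_ref: float,
               cfg: LoopConfig | None = None,
               rng: np.random.Generator | None = None,
               seg_a: int = -1, seg_b: int = -1,
               guide: DensityMap | None = None) -> LoopCandidate:
    """Close a CA-trace loop of ``n_res`` interior residues between two
    anchor CAs, guided by the density map.

    Randomly perturbed piecewise-linear paths are alternately projected
    onto local density maxima (within 1 Å) and onto the CA-step-length
    manifold; the densest converged trace is kept.  When a ``guide`` map is
    given (typically the map minus the current model's density) the
    projection follows it instead of the raw map, so the trace is drawn to
    *unexplained* density rather than to the already-built neighbours.  The
    loop is accepted when its mean trace density in the map reaches
    ``f_loop`` times ``rho_ref`` (the model's global mean residue density).
    Deterministic for a fixed rng.
    """
    cfg = cfg or LoopConfig()
    rng = rng or np.random.default_rng(0)
    if guide is None:
        guide = dmap
    anchor_a = np.asarray(anchor_a, float)
    anchor_b = np.asarray(anchor_b, float)
    span = float(np.linalg.norm(anchor_b - anchor_a))
    if span > (n_res + 1) * CA_STEP_MAX:
        return LoopCandidate(seg_a, seg_b, n_res, anchor_a, anchor_b,
                             np.empty((0, 3)), 0.0, False,
                             reason="span_too_long")
    if n_res == 0:
        mid = 0.5 * (anchor_a + anchor_b)
        dens = float(interpolate(dmap, mid)) if dmap.contains(mid)[0] else 0.0
        ok = dens >= cfg.f_loop * rho_ref and span <= CA_STEP_MAX + 0.5
        return LoopCandidate(seg_a, seg_b, 0, anchor_a, anchor_b,
                             np.empty((0, 3)), dens, ok,
                             reason="" if ok else "low_density")
    best_trace, best_dens, best_gdens = None, -np.inf, -np.inf
    t = np.linspace(0, 1, n_res + 2)[1:-1, None]
    base = anchor_a + t * (anchor_b - anchor_a)
    starts: list[tuple[np.ndarray, float]] = []
    dp = _densest_lattice_path(guide, anchor_a, anchor_b, n_res, cfg)
    if dp is not None:
        # the deterministic lattice optimum, gently refined off-lattice
        starts.append((dp, 0.5))
    for _ in range(cfg.n_trials):
        starts.append((base + rng.normal(0, 1.0, (n_res, 3)), 1.0))
    for interior, radius in starts:
        path = np.vstack([anchor_a[None], interior, anchor_b[None]])
        converged = False
        for _ in range(6):
            _project_density(path, guide, radius=radius)
            converged = _project_steps(path, cfg.max_project_iter)
        if not converged:
            continue
        inside = dmap.contains(path[1:-1])
        if not np.all(inside):
            continue
        # trials compete on unexplained (guide) density; acceptance is
        # judged on the map itself
        gdens = float(np.mean(interpolate(guide, path[1:-1])))
        if gdens > best_gdens:
            best_gdens = gdens
            best_dens = float(np.mean(interpolate(dmap, path[1:-1])))
            best_trace = path[1:-1].copy()
    if best_trace is None:
        return LoopCandidate(seg_a, seg_b, n_res, anchor_a, anchor_b,
                             np.empty((0, 3)), 0.0, False, reason="no_closure")
    accepted = best_dens >= cfg.f_loop * rho_ref
    return LoopCandidate(seg_a, seg_b, n_res, anchor_a, anchor_b, best_trace,
                         best_dens, accepted,
                         reason="" if accepted else "low_density")


# --------------------------------------------------------------------------
# Merging loops into the model
# --------------------------------------------------------------------------

def _loop_backbone(path: np.ndarray, j: int) -> list[Atom]:
    """Crude backbone (N, CA, C, O) for interior trace point j of a full
    CA path; good enough to anchor the next extraction round."""
    ca = path[j]
    to_prev = path[j - 1] - ca
    to_next = path[j + 1] - ca
    n_pos = ca + 1.46 * to_prev / np.linalg.norm(to_prev)
    c_pos = ca + 1.52 * to_next / np.linalg.norm(to_next)
    axis = path[j + 1] - path[j - 1]
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    o_pos = c_pos + 1.23 * perp
    return [Atom("N", "N", n_pos), Atom("CA", "C", ca),
            Atom("C", "C", c_pos), Atom("O", "O", o_pos)]


def merge_with_loops(model: AtomicModel, state: AssignmentState,
                     segments: list[Segment],
                     accepted_loops: dict[tuple[int, int, int], LoopCandidate],
                     seq: TargetSequence) -> AtomicModel:
    """Build the next-round model from the winning assignment.

    ``model`` must already have residue types applied
    (see :func:`morphassign.assign.apply_assignment`).  Assigned segments
    are renumbered to their target-sequence positions in chain A; accepted
    loops whose length matches the assigned gap are inserted as backbone
    residues, joining segments into longer ones.  Unassigned segments are
    kept unchanged in chain U.
    """
    lookup = {(ch.id, r.seqid): r for ch, r in model.residues()}
    segs = {s.index: s for s in segments}
    placed = sorted(state.assignment.items(), key=lambda kv: kv[1])
    chain_a = Chain("A")
    for k, (si, offset) in enumerate(placed):
        seg = segs[si]
        for i, key in enumerate(seg.keys()):
            res = lookup[key]
            res.seqid = offset + i + 1
            chain_a.residues.append(res)
        if k + 1 < len(placed):
            ni, no = placed[k + 1]
            gap = no - (offset + seg.n)
            loop = accepted_loops.get((si, ni, gap))
            if loop is not None and loop.accepted and loop.n_res == gap:
                nseg = segs[ni]
                path = np.vstack([seg.c_end[None], loop.trace,
                                  nseg.n_end[None]])
                for j in range(1, gap + 1):
                    pos = offset + seg.n + (j - 1)
                    res = Residue(seqid=pos + 1,
                                  name=AA1_TO_3.get(seq[pos], "UNK"),
                                  assigned_pos=pos)
                    res.atoms = _loop_backbone(path, j)
                    chain_a.residues.append(res)
    out = AtomicModel()
    if chain_a.residues:
        out.chains.append(chain_a)
    unassigned = [s for s in segments if s.index not in state.assignment]
    if unassigned:
        chain_u = Chain("U")
        for seg in unassigned:
            for key in seg.keys():
                chain_u.residues.append(lookup[key])
        out.chains.append(chain_u)
    return out.copy()


# --------------------------------------------------------------------------
# Iterated assignment
# --------------------------------------------------------------------------

def iterate_assignment(model: AtomicModel, dmap: DensityMap,
                       seq: TargetSequence,
                       score_cfg: ScoreConfig | None = None,
                       loop_cfg: LoopConfig | None = None,
                       constraints: Constraints | None = None,
                       n_iter: int = 3, seed: int = 0
                       ) -> tuple[AtomicModel, list[dict]]:
    """Repeat {extract segments, place, optimise, build loops, merge}.

    Each iteration may connect segments with newly validated loops, which
    lengthens segments and typically lets the next round assign more
    residues.  Returns the final model (chain A assigned/merged, chain U
    unassigned) and a per-iteration history of counts.
    """
    score_cfg = score_cfg or ScoreConfig()
    loop_cfg = loop_cfg or LoopConfig()
    constraints = constraints or Constraints()
    work = model.copy()
    history: list[dict] = []
    prev_state: AssignmentState | None = None
    for it in range(n_iter):
        segments = extract_segments(work, score_cfg.min_segment_length)
        if not segments:
            history.append({"iteration": it + 1, "n_built": work.n_residues,
                            "n_assigned": 0, "n_segments": 0, "score": 0.0})
            break
        matrix = build_placement_matrix(segments, dmap, seq, score_cfg)
        model_density = rasterize(work, like=dmap)
        rho_ref = residue_stats(dmap, work,
                                model_density=model_density).rho_mean_all
        # loops are traced through density not yet explained by the model
        guide = DensityMap(dmap.values - model_density.values,
                           dmap.spacing, dmap.origin)
        rng = np.random.default_rng((seed + 77_003 * (it + 1)) % (2 ** 31))

        validated: dict[tuple[int, int, int], LoopCandidate] = {}
        if constraints.use_loops:
            state0 = optimize(segments, matrix, seq, score_cfg, constraints)
            first = state0[0] if state0 else None
            pairs = propose_loop_pairs(segments, first, loop_cfg)
            segs = {s.index: s for s in segments}
            for sa, sb, gap in pairs:
                a, b = segs[sa], segs[sb]
                span = float(np.linalg.norm(b.n_end - a.c_end))
                if gap is not None:
                    lengths = [gap]
                else:
                    n_min = max(0, int(np.ceil(span / CA_STEP_MAX)) - 1)
                    lengths = range(n_min,
                                    n_min + loop_cfg.max_extra_residues + 1)
                for n_res in lengths:
                    key = (sa, sb, n_res)
                    if key in validated:
                        continue
                    ok, _ = connection_feasible(a.c_end, b.n_end, n_res,
                                                score_cfg.max_span_per_residue)
                    if not ok:
                        continue
                    cand = build_loop(a.c_end, b.n_end, n_res, dmap, rho_ref,
                                      loop_cfg, rng, sa, sb, guide=guide)
                    if cand.accepted:
                        validated[key] = cand

        states = optimize(segments, matrix, seq, score_cfg, constraints,
                          validated_loops=validated or None)
        state = states[0] if states else AssignmentState({})
        n_assigned = sum(segs_n for segs_n in
                         (next(s.n for s in segments if s.index == si)
                          for si in state.assignment))
        history.append({"iteration": it + 1, "n_built": work.n_residues,
                        "n_assigned": n_assigned,
                        "n_segments": len(segments),
                        "n_loops": len(validated),
                        "score": state.score})
        logger.info("assignment iteration %d: %d segments, %d/%d residues "
                    "assigned, %d loops, score %.2f", it + 1, len(segments),
                    n_assigned, work.n_residues, len(validated), state.score)
        assigned_model = apply_assignment(work, state, segments, seq)
        new_work = merge_with_loops(assigned_model, state, segments,
                                    {k: v for k, v in validated.items()},
                                    seq)
        if prev_state is not None and state.key() == prev_state.key() \
                and not validated:
            work = new_work
            break
        prev_state = state
        work = new_work
    return work, history
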