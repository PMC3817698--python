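"""Sequence assignment of trimmed segments.

Each maximal contiguous segment of the trimmed model is assigned an offset
in the target sequence by maximising an additive target function:

* density term: log of the estimated probability that the placement is
  correct, from side-chain density at each residue's probe position;
* connection terms: a placement is rejected outright when the distance
  between the ends of sequence-adjacent segments exceeds what the
  intervening residues can span; feasible connections get a small
  closeness reward;
* loop bonuses (typically 10 units) when a validated density-consistent
  loop of exactly the assigned gap length connects two segments;
* a template-sequence term: the BLOSUM62 Z-score of the assigned sequence
  against the segment's template sequence, floored at zero.

Constraints: no sequence residue may be used more than ``ncs_copies``
times, and (optionally) segment order must match template order.  The
search is exhaustive when the pruned enumeration is small enough and a
deterministic beam search otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from pydantic import BaseModel, Field

from . import constants as C
from .density import DensityMap, interpolate
from .structure_io import AtomicModel, Residue, TargetSequence, contiguous_runs
from .synthetic import ideal_cb

__all__ = [
    "Segment", "PlacementMatrix", "ScoreConfig", "Constraints",
    "AssignmentState", "extract_segments", "sidechain_placement_probs",
    "build_placement_matrix", "density_term", "connection_feasible",
    "template_zscore", "loop_bonus_term", "total_score", "optimize",
    "apply_assignment",
]

REJECTED = float("-inf")


class ScoreConfig(BaseModel):
    """Weights and limits of the assignment target function."""
    loop_bonus: float = Field(10.0, ge=0)
    w_template: float = Field(1.0, ge=0)
    max_span_per_residue: float = Field(3.8, ge=3.3, le=4.0)
    beam_width: int = Field(50, ge=1)
    min_segment_length: int = Field(4, ge=1)
    exhaustive_limit: int = Field(100_000, ge=1)
    top_k_offsets: int = Field(16, ge=1)
    prob_sharpness: float = Field(0.25, gt=0)


class Constraints(BaseModel):
    """Which information sources the optimiser enforces/uses."""
    non_overlap: bool = True
    order: bool = True
    connection: bool = True
    use_loops: bool = True


@dataclass
class Segment:
    """A maximal contiguous run of residues of the trimmed model."""
    index: int
    chain_id: str
    residues: list[Residue]

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def n_end(self) -> np.ndarray:
        """CA position of the first (N-terminal) residue."""
        return self.residues[0].ca.pos

    @property
    def c_end(self) -> np.ndarray:
        return self.residues[-1].ca.pos

    @property
    def template_seq(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def template_order(self) -> int:
        """Position of the segment in the template chain (for the order
        constraint); falls back to the first residue number."""
        for r in self.residues:
            if r.template_index is not None:
                return r.template_index
        return self.residues[0].seqid

    def keys(self) -> list[tuple[str, int]]:
        return [(self.chain_id, r.seqid) for r in self.residues]


def extract_segments(model: AtomicModel, min_len: int = 4) -> list[Segment]:
    """Maximal runs of consecutive residues (numbering gaps and CA-CA
    breaks split); runs shorter than ``min_len`` are dropped."""
    segments: list[Segment] = []
    for ch in model.chains:
        for run in contiguous_runs(ch):
            run = [r for r in run if r.ca is not None]
            if len(run) >= min_len:
                segments.append(Segment(len(segments), ch.id, run))
    return segments


# --------------------------------------------------------------------------
# Side-chain density probabilities
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)

# fixed quadrature for the 2 Å probe sphere: centre + two shells
_PROBE_OFFSETS = np.vstack([np.zeros((1, 3)),
                            1.0 * _fibonacci_sphere(12),
                            1.8 * _fibonacci_sphere(20)])

PROBE_DISTANCE = 2.4   # Å from CA along CA->CB
PROBE_RADIUS = 2.0     # Å, radius of the probe sphere


def sidechain_probe_density(res: Residue, dmap: DensityMap) -> float:
    """Mean map density in the side-chain probe region of a residue.

    The probe is a 2 Å sphere centred 2.4 Å from CA along the CA->CB
    direction (an ideal CB is built from the backbone for Gly or a missing
    CB).  Out-of-map quadrature points are ignored.
    """
    ca = res.ca
    cb = res.atom("CB")
    if cb is not None:
        u = cb.pos - ca.pos
    else:
        n, c = res.atom("N"), res.atom("C")
        if n is None or c is None:
            return float(interpolate(dmap, ca.pos))
        u = ideal_cb(n.pos, ca.pos, c.pos) - ca.pos
    u = u / np.linalg.norm(u)
    center = ca.pos + PROBE_DISTANCE * u
    pts = center + _PROBE_OFFSETS
    ok = dmap.contains(pts)
    if not np.any(ok):
        return 0.0
    return float(np.mean(interpolate(dmap, pts[ok])))


_SIZE_Z = {a: (C.SIDECHAIN_ELECTRONS[a] - C.SIDECHAIN_ELECTRONS_MEAN)
           / C.SIDECHAIN_ELECTRONS_SD for a in C.SIDECHAIN_ELECTRONS}


def sidechain_placement_probs(segment: Segment, dmap: DensityMap,
                              seq: TargetSequence,
                              sharpness: float = 0.25
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Probability of each sequence offset for one segment.

    Per-residue probe densities are z-scored within the segment and
    correlated with the z-scored side-chain sizes of the candidate target
    residues (a declared monotone model of density vs residue size: bigger
    side chains put more electrons in the probe).  The per-offset sums are
    converted to probabilities with a softmax of the given sharpness.

    Returns (offsets, probabilities); both empty when the segment is longer
    than the sequence.
    """
    L, n = len(seq), segment.n
    if n > L:
        return np.empty(0, int), np.empty(0)
    offsets = np.arange(L - n + 1)
    s = np.array([sidechain_probe_density(r, dmap) for r in segment.residues])
    sd = s.std()
    s_hat = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    size_z = np.array([_SIZE_Z.get(a, 0.0) for a in seq.sequence])
    # windowed dot product of s_hat with size_z at every offset
    scores = np.array([float(s_hat @ size_z[o:o + n]) for o in offsets])
    logits = sharpness * scores
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return offsets, p


@dataclass
class PlacementMatrix:
    """Per-segment offset probabilities (and cached static scores)."""
    rows: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def p(self, seg_index: int, offset: int) -> float:
        offsets, probs = self.rows[seg_index]
        i = np.searchsorted(offsets, offset)
        if i >= len(offsets) or offsets[i] != offset:
            return 0.0
        return float(probs[i])

    def best_p(self, seg_index: int) -> float:
        _, probs = self.rows[seg_index]
        return float(probs.max()) if len(probs) else 0.0


def build_placement_matrix(segments: list[Segment], dmap: DensityMap,
                           seq: TargetSequence,
                           cfg: ScoreConfig | None = None) -> PlacementMatrix:
    cfg = cfg or ScoreConfig()
    m = PlacementMatrix()
    for seg in segments:
        m.rows[seg.index] = sidechain_placement_probs(
            seg, dmap, seq, cfg.prob_sharpness)
    return m


# --------------------------------------------------------------------------
# Score terms
# --------------------------------------------------------------------------

P_FLOOR = 1e-12
P_CEIL = 1.0 - 1e-9


def density_term(p: float) -> float:
    """ln of the estimated probability of a correct placement."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return math.log(min(max(p, P_FLOOR), P_CEIL))


def connection_feasible(end_a: np.ndarray, end_b: np.ndarray, gap: int,
                        max_span_per_residue: float = 3.8
                        ) -> tuple[bool, float]:
    """Feasibility and closeness term for a link of ``gap`` sequence
    residues between two segment ends.

    Infeasible (rejected) when the end-to-end distance exceeds
    (gap + 1) * max_span_per_residue; feasible links score -d / limit,
    a small reward in [-1, 0] for ends that are close.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    d = float(np.linalg.norm(np.asarray(end_a) - np.asarray(end_b)))
    limit = (gap + 1) * max_span_per_residue
    if d > limit:
        return False, 0.0
    return True, -d / limit


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62 = np.full((26, 26), 0.0)
for _a in C.STANDARD_AA1 + "X":
    for _b in C.STANDARD_AA1 + "X":
        _B62[ord(_a) - 65, ord(_b) - 65] = _BLOSUM62[_a][_b]


@lru_cache(maxsize=4096)
def _blosum_profile(template_seq: str, target: str) -> np.ndarray:
    """Gapless BLOSUM62 scores of the template segment at every target
    offset (cached: the optimiser evaluates the same pair many times)."""
    n, L = len(template_seq), len(target)
    if n > L:
        return np.empty(0)
    ti = np.array([ord(c) - 65 for c in template_seq])
    si = np.array([ord(c) - 65 for c in target])
    out = np.empty(L - n + 1)
    for o in range(L - n + 1):
        out[o] = _B62[ti, si[o:o + n]].sum()
    return out


def template_zscore(template_seq: str, target_seq: str, offset: int) -> float:
    """Z-score of the gapless BLOSUM62 match at ``offset``, relative to the
    distribution of the match score over all possible offsets of the
    segment in the target sequence; floored at zero."""
    scores = _blosum_profile(template_seq.upper(), target_seq.upper())
    if len(scores) < 2:
        return 0.0
    mu, sd = scores.mean(), scores.std()
    if sd == 0:
        return 0.0
    return max(float((scores[offset] - mu) / sd), 0.0)


def loop_bonus_term(seg_a: int, seg_b: int, gap: int,
                    validated_loops: dict | None,
                    loop_bonus: float = 10.0) -> float:
    """Bonus when a validated loop of exactly ``gap`` residues connects
    seg_a's C-end to seg_b's N-end."""
    if validated_loops and (seg_a, seg_b, gap) in validated_loops:
        return loop_bonus
    return 0.0


# --------------------------------------------------------------------------
# Assignment states and the total score
# --------------------------------------------------------------------------

@dataclass
class AssignmentState:
    """A (partial) assignment of segments to sequence offsets."""
    assignment: dict[int, int]          # segment index -> offset (0-based)
    score: float = 0.0
    breakdown: dict[str, float] = field(default_factory=dict)
    valid: bool = True

    def key(self) -> tuple:
        return tuple(sorted(self.assignment.items()))


def _check_constraints(assignment: dict[int, int], segments_by_id: dict,
                       seq_len: int, ncs_copies: int,
                       constraints: Constraints) -> bool:
    if constraints.non_overlap:
        usage = np.zeros(seq_len, dtype=int)
        for si, o in assignment.items():
            n = segments_by_id[si].n
            if o < 0 or o + n > seq_len:
                return False
            usage[o:o + n] += 1
        if usage.max(initial=0) > ncs_copies:
            return False
    if constraints.order and len(assignment) > 1:
        items = sorted(assignment.items(),
                       key=lambda kv: segments_by_id[kv[0]].template_order)
        offs = [o for _, o in items]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            return False
    return True


def total_score(state: AssignmentState, segments: list[Segment],
                matrix: PlacementMatrix, seq: TargetSequence,
                cfg: ScoreConfig, constraints: Constraints | None = None,
                validated_loops: dict | None = None) -> float:
    """Additive target function; -inf for states violating a constraint.

    Also refreshes ``state.breakdown``; the total equals the exact sum of
    the breakdown terms.
    """
    constraints = constraints or Constraints()
    segs = {s.index: s for s in segments}
    if not _check_constraints(state.assignment, segs, len(seq),
                              seq.ncs_copies, constraints):
        state.score = REJECTED
        state.valid = False
        return REJECTED
    bd = {"density": 0.0, "template": 0.0, "connection": 0.0, "loops": 0.0}
    for si, o in state.assignment.items():
        bd["density"] += density_term(matrix.p(si, o))
        if cfg.w_template > 0:
            bd["template"] += cfg.w_template * template_zscore(
                segs[si].template_seq, seq.sequence, o)
    if constraints.connection and seq.ncs_copies == 1:
        placed = sorted(state.assignment.items(), key=lambda kv: kv[1])
        for (ai, ao), (bi, bo) in zip(placed, placed[1:]):
            gap = bo - (ao + segs[ai].n)
            if gap < 0:
                continue  # overlap beyond copies already rejected above
            ok, term = connection_feasible(segs[ai].c_end, segs[bi].n_end,
                                           gap, cfg.max_span_per_residue)
            if not ok:
                state.score = REJECTED
                state.valid = False
                return REJECTED
            bd["connection"] += term
            if constraints.use_loops:
                bd["loops"] += loop_bonus_term(ai, bi, gap, validated_loops,
                                               cfg.loop_bonus)
    state.breakdown = bd
    state.score = sum(bd.values())
    state.valid = True
    return state.score


# --------------------------------------------------------------------------
# Optimisation
# --------------------------------------------------------------------------

def _candidate_offsets(seg: Segment, matrix: PlacementMatrix,
                       seq: TargetSequence, cfg: ScoreConfig) -> list[int]:
    """Offsets of one segment ranked by static score (density + template),
    truncated to top_k."""
    offsets, probs = matrix.rows[seg.index]
    if len(offsets) == 0:
        return []
    static = np.array([density_term(p) for p in probs])
    if cfg.w_template > 0:
        zprof = _blosum_profile(seg.template_seq, seq.sequence)
        if len(zprof) >= 2 and zprof.std() > 0:
            z = np.maximum((zprof - zprof.mean()) / zprof.std(), 0.0)
            static = static + cfg.w_template * z
    order = np.lexsort((offsets, -static))
    return [int(offsets[i]) for i in order[:cfg.top_k_offsets]]


def _exhaustive(segments, cands, segs_by_id, matrix, seq, cfg, constraints,
                validated_loops, node_budget):
    """Depth-first enumeration over segments in template order.

    Order and overlap constraints prune incrementally; complete leaves are
    scored with :func:`total_score` (which re-checks everything).  Returns
    (states, completed); completed is False if the node budget was
    exhausted, in which case the caller falls back to beam search."""
    order = sorted(segments, key=lambda s: s.template_order)
    results: list[AssignmentState] = []
    usage = np.zeros(len(seq), dtype=int)
    nodes = 0

    def recurse(i: int, last_offset: int, assignment: dict[int, int]) -> bool:
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            return False
        if i == len(order):
            st = AssignmentState(dict(assignment))
            sc = total_score(st, segments, matrix, seq, cfg, constraints,
                             validated_loops)
            if sc > REJECTED:
                results.append(st)
            return True
        seg = order[i]
        if not recurse(i + 1, last_offset, assignment):   # leave unassigned
            return False
        for o in sorted(cands[seg.index]):
            if constraints.order and o <= last_offset:
                continue
            if o + seg.n > len(seq):
                continue
            if constraints.non_overlap:
                usage[o:o + seg.n] += 1
                ok = usage[o:o + seg.n].max() <= seq.ncs_copies
            else:
                ok = True
            if ok:
                assignment[seg.index] = o
                done = recurse(i + 1, o if constraints.order else last_offset,
                               assignment)
                del assignment[seg.index]
            else:
                done = True
            if constraints.non_overlap:
                usage[o:o + seg.n] -= 1
            if not done:
                return False
        return True

    completed = recurse(0, -1, {})
    return results, completed


def _beam(segments, cands, segs_by_id, matrix, seq, cfg, constraints,
          validated_loops):
    """Deterministic beam search over partial assignments."""
    seen: dict[tuple, AssignmentState] = {}

    def make_state(assignment: dict[int, int]) -> AssignmentState | None:
        st = AssignmentState(dict(assignment))
        key = st.key()
        if key in seen:
            return None
        sc = total_score(st, segments, matrix, seq, cfg, constraints,
                         validated_loops)
        if sc == REJECTED:
            return None
        seen[key] = st
        return st

    beam = [make_state({})]
    for _ in range(len(segments)):
        pool: list[AssignmentState] = []
        for st in beam:
            if st is None:
                continue
            for seg in segments:
                if seg.index in st.assignment:
                    continue
                for o in cands[seg.index]:
                    new = dict(st.assignment)
                    new[seg.index] = o
                    made = make_state(new)
                    if made is not None:
                        pool.append(made)
        if not pool:
            break
        pool.sort(key=lambda s: _rank_key(s, segs_by_id))
        beam = pool[:cfg.beam_width]
    states = list(seen.values())
    return states


def _rank_key(state: AssignmentState, segs_by_id: dict):
    """Deterministic ranking of candidate states.

    The optimiser grows assignments as far as the constraints allow:
    coverage (assigned residues) ranks first, so a segment is left out only
    when every placement is rejected; among states with equal coverage the
    additive score decides (quantised so numerically negligible differences
    cannot flip the order), then (segment, offset) lexicographic order."""
    n_assigned = sum(segs_by_id[si].n for si in state.assignment)
    return (-n_assigned, -round(state.score, 6), state.key())


def optimize(segments: list[Segment], matrix: PlacementMatrix,
             seq: TargetSequence, cfg: ScoreConfig | None = None,
             constraints: Constraints | None = None,
             validated_loops: dict | None = None,
             n_best: int = 5) -> list[AssignmentState]:
    """Find the highest-scoring assignments of segments to offsets.

    Runs pruned exhaustive enumeration when the search tree fits in
    ``exhaustive_limit`` nodes, otherwise a deterministic beam search
    (width ``beam_width``) that grows assignments one segment at a time.
    Segments may remain unassigned (contributing nothing).  Returns states
    ranked by score with deterministic tie-breaking.
    """
    cfg = cfg or ScoreConfig()
    constraints = constraints or Constraints()
    if not segments:
        return []
    segs_by_id = {s.index: s for s in segments}
    cands = {s.index: _candidate_offsets(s, matrix, seq, cfg)
             for s in segments}
    n_combos = 1.0
    for s in segments:
        n_combos *= len(cands[s.index]) + 1
    completed = False
    if n_combos <= cfg.exhaustive_limit:
        states, completed = _exhaustive(
            segments, cands, segs_by_id, matrix, seq, cfg, constraints,
            validated_loops, node_budget=4 * cfg.exhaustive_limit)
    if not completed:
        states = _beam(segments, cands, segs_by_id, matrix, seq, cfg,
                       constraints, validated_loops)
    states.sort(key=lambda s: _rank_key(s, segs_by_id))
    return states[:n_best]


# --------------------------------------------------------------------------
# Applying an assignment
# --------------------------------------------------------------------------

def apply_assignment(model: AtomicModel, state: AssignmentState,
                     segments: list[Segment], seq: TargetSequence
                     ) -> AtomicModel:
    """Mutate residue types of assigned segments to the target sequence.

    Backbone coordinates are untouched; side-chain atoms beyond CB are
    dropped for residues whose type changes.  Unassigned segments keep
    their template types and stay flagged (assigned_pos is None).
    """
    out = model.copy()
    lookup = {(ch.id, r.seqid): r for ch, r in out.residues()}
    segs = {s.index: s for s in segments}
    for si, offset in state.assignment.items():
        seg = segs[si]
        for i, key in enumerate(seg.keys()):
            res = lookup[key]
            pos = offset + i
            res.assigned_pos = pos
            new_aa = seq[pos]
            if new_aa != res.one_letter:
                res.name = C.AA1_TO_3.get(new_aa, "UNK")
                res.atoms = [a for a in res.atoms
                             if a.name in ("N", "CA", "C", "O", "CB")]
    return out
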