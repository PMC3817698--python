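"""Segment extraction, scoring terms and the assignment optimiser."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from morphassign.assign import (AssignmentState, Constraints, PlacementMatrix,
                                ScoreConfig, Segment, apply_assignment,
                                build_placement_matrix, connection_feasible,
                                density_term, extract_segments, optimize,
                                sidechain_placement_probs, template_zscore,
                                total_score)
from morphassign.structure_io import (Atom, AtomicModel, Chain, Residue,
                                      TargetSequence)
from morphassign.synthetic import make_map, make_truth, perturb_template


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

def test_extract_segments_rules():
    model, _ = make_truth(50, seed=2)
    assert len(extract_segments(model)) == 1

    model2, _ = make_truth(20, seed=2)
    ch = model2.chains[0]
    # residues 1-10 and 15-20
    ch.residues = ch.residues[:10] + ch.residues[14:]
    segs = extract_segments(model2)
    assert [s.n for s in segs] == [10, 6]

    model3, _ = make_truth(12, seed=2)
    ch3 = model3.chains[0]
    ch3.residues = ch3.residues[:3] + ch3.residues[8:]
    segs3 = extract_segments(model3, min_len=4)
    assert [s.n for s in segs3] == [4]          # run of 3 dropped


# --------------------------------------------------------------------------
# placement probabilities
# --------------------------------------------------------------------------

def _segment_from(model, lo, hi, index=0):
    return Segment(index, "A", model.chains[0].residues[lo:hi])


def test_homopolymer_gives_uniform_probabilities():
    model, _ = make_truth(30, seed=4)
    for _, r in model.residues():
        r.name = "ALA"
    dmap = make_map(model)
    seg = _segment_from(model, 5, 15)
    offsets, p = sidechain_placement_probs(seg, dmap,
                                           TargetSequence("A" * 30))
    assert p == pytest.approx(np.full(len(offsets), 1 / len(offsets)))
    assert p.sum() == pytest.approx(1.0)


def test_motif_locates_true_offset():
    """Large aromatic side chains at two known positions pin the register."""
    model, seq = make_truth(40, seed=9)
    ch = model.chains[0]
    letters = list(seq.sequence)
    for i in range(40):
        letters[i] = "A"
    for i, r in enumerate(ch.residues):
        r.name = "ALA"
    # put Trp at 13 and Phe at 19 (segment positions 3 and 9 of [10:22))
    from morphassign.synthetic import _sidechain_atoms
    for pos, aa in ((13, "W"), (19, "F")):
        r = ch.residues[pos]
        r.name = {"W": "TRP", "F": "PHE"}[aa]
        letters[pos] = aa
        r.atoms = [a for a in r.atoms if a.name in ("N", "CA", "C", "O")]
        r.atoms.extend(_sidechain_atoms(aa, r.atom("N").pos, r.atom("CA").pos,
                                        r.atom("C").pos))
    target = TargetSequence("".join(letters))
    dmap = make_map(model)
    seg = _segment_from(model, 10, 22)
    offsets, p = sidechain_placement_probs(seg, dmap, target)
    assert offsets[int(np.argmax(p))] == 10
    assert p.sum() == pytest.approx(1.0)


def test_segment_longer_than_sequence_empty_row():
    model, _ = make_truth(30, seed=4)
    dmap = make_map(model)
    seg = _segment_from(model, 0, 30)
    offsets, p = sidechain_placement_probs(seg, dmap, TargetSequence("ACDE"))
    assert len(offsets) == 0 and len(p) == 0


# --------------------------------------------------------------------------
# score terms
# --------------------------------------------------------------------------

def test_density_term_values():
    diff = density_term(0.95) - density_term(0.05)
    assert diff == pytest.approx(math.log(19), abs=1e-9)
    assert density_term(1.0) == pytest.approx(0.0, abs=1e-8)
    assert density_term(0.3) == density_term(0.3)
    with pytest.raises(ValueError):
        density_term(1.5)


def test_connection_feasibility_arithmetic():
    a, b = np.zeros(3), np.array([10.0, 0, 0])
    ok, term = connection_feasible(a, b, 2)     # 3 * 3.8 = 11.4 >= 10
    assert ok and -1.0 <= term <= 0.0
    ok1, _ = connection_feasible(a, b, 1)       # 2 * 3.8 = 7.6 < 10
    assert not ok1
    ok0, term0 = connection_feasible(a, a, 0)
    assert ok0 and term0 == pytest.approx(0.0)


def test_template_zscore_against_bruteforce():
    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(3)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        target = "".join(rng.choice(list(aas), 40))
        tmpl = "".join(rng.choice(list(aas), 10))
        offset = int(rng.integers(0, 31))
        # independent enumeration of the alignment-score distribution
        scores = [sum(blosum[a][b] for a, b in zip(tmpl, target[o:o + 10]))
                  for o in range(31)]
        mu, sd = np.mean(scores), np.std(scores)
        expected = max((scores[offset] - mu) / sd, 0.0) if sd > 0 else 0.0
        assert template_zscore(tmpl, target, offset) == pytest.approx(expected)


def test_template_zscore_self_match_positive_and_floor():
    target = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEW"
    tmpl = target[10:20]
    assert template_zscore(tmpl, target, 10) > 0
    # a mismatched register scoring below the mean is floored at zero
    zs = [template_zscore(tmpl, target, o) for o in range(len(target) - 9)]
    assert min(zs) == 0.0


# --------------------------------------------------------------------------
# total score and the optimiser
# --------------------------------------------------------------------------

def _toy_problem(seq_len=30, seg_lens=(6, 5), spread=40.0):
    """Segments as straight CA chains far apart, plus a uniform matrix."""
    segments = []
    model = AtomicModel([Chain("A")])
    seqid = 1
    for k, n in enumerate(seg_lens):
        residues = []
        for i in range(n):
            r = Residue(seqid=seqid, name="ALA", template_index=seqid)
            r.atoms.append(Atom("CA", "C",
                                [spread * k + 3.8 * i, 0.0, 0.0]))
            residues.append(r)
            seqid += 1
        seqid += 5   # numbering gap between segments
        model.chains[0].residues.extend(residues)
        segments.append(Segment(k, "A", residues))
    return model, segments


def _matrix_for(segments, seq_len, rows):
    m = PlacementMatrix()
    for seg, row in zip(segments, rows):
        offsets = np.arange(seq_len - seg.n + 1)
        p = np.asarray(row, float)
        m.rows[seg.index] = (offsets, p / p.sum())
    return m


def brute_force_best(segments, matrix, seq, cfg, constraints, loops=None):
    """Independent enumeration over every full/partial assignment.

    Mirrors the optimiser's preference: maximal residue coverage first,
    then the additive score.  Returns (n_assigned_residues, score)."""
    option_lists = []
    for seg in segments:
        offsets, _ = matrix.rows[seg.index]
        option_lists.append([None] + list(offsets))
    best = (0, 0.0)
    for combo in itertools.product(*option_lists):
        assignment = {seg.index: o for seg, o in zip(segments, combo)
                      if o is not None}
        st = AssignmentState(assignment)
        sc = total_score(st, segments, matrix, seq, cfg, constraints, loops)
        if sc == float("-inf"):
            continue
        cov = sum(seg.n for seg, o in zip(segments, combo) if o is not None)
        if (cov, sc) > best:
            best = (cov, sc)
    return best


def test_single_segment_takes_argmax():
    _, segments = _toy_problem(seg_lens=(6,))
    seq = TargetSequence("A" * 30)
    row = np.ones(25)
    row[17] = 50.0
    m = _matrix_for(segments, 30, [row])
    cfg = ScoreConfig(w_template=0.0, top_k_offsets=30)
    states = optimize(segments, m, seq, cfg)
    assert states[0].assignment == {0: 17}


@pytest.mark.parametrize("order", [True, False])
def test_optimizer_matches_bruteforce(order):
    rng = np.random.default_rng(42)
    seq = TargetSequence("A" * 12)
    cfg = ScoreConfig(w_template=0.0, top_k_offsets=8)
    constraints = Constraints(order=order)
    for _ in range(10):
        seg_lens = rng.integers(4, 6, size=int(rng.integers(1, 4)))
        model, segments = _toy_problem(seq_len=12, seg_lens=tuple(seg_lens))
        rows = [rng.random(12 - s.n + 1) + 0.05 for s in segments]
        m = _matrix_for(segments, 12, rows)
        states = optimize(segments, m, seq, cfg, constraints)
        exp_cov, exp_score = brute_force_best(segments, m, seq, cfg,
                                              constraints)
        st = states[0]
        got_cov = sum(s.n for s in segments if s.index in st.assignment)
        assert got_cov == exp_cov
        assert st.score == pytest.approx(exp_score)


def test_overlap_forces_relocation():
    """When B's density argmax overlaps A's span, the joint optimum moves B
    to its runner-up (true) offset."""
    _, segments = _toy_problem(seq_len=30, seg_lens=(8, 8))
    seq = TargetSequence("A" * 30)
    row_a = np.full(23, 0.01)
    row_a[2] = 10.0
    row_b = np.full(23, 0.01)
    row_b[4] = 10.0    # overlaps A's span 2..10
    row_b[14] = 8.0    # non-overlapping alternative
    m = _matrix_for(segments, 30, [row_a, row_b])
    cfg = ScoreConfig(w_template=0.0, top_k_offsets=23)
    free = optimize(segments, m, seq, cfg,
                    Constraints(non_overlap=False, order=False,
                                connection=False))
    assert free[0].assignment == {0: 2, 1: 4}
    constrained = optimize(segments, m, seq, cfg,
                           Constraints(order=False, connection=False))
    assert constrained[0].assignment == {0: 2, 1: 14}


def test_ncs_copies_allow_reuse():
    _, segments = _toy_problem(seq_len=20, seg_lens=(8, 8))
    row = np.full(13, 0.01)
    row[3] = 10.0
    m = _matrix_for(segments, 20, [row, row.copy()])
    cfg = ScoreConfig(w_template=0.0, top_k_offsets=13)
    cons = Constraints(order=False, connection=False)
    single = optimize(segments, m, TargetSequence("A" * 20), cfg, cons)
    assert single[0].assignment != {0: 3, 1: 3}
    double = optimize(segments, m, TargetSequence("A" * 20, ncs_copies=2),
                      cfg, cons)
    assert double[0].assignment == {0: 3, 1: 3}


def test_order_constraint_rejects_swaps():
    _, segments = _toy_problem(seq_len=30, seg_lens=(6, 6))
    seq = TargetSequence("A" * 30)
    row_a = np.full(25, 0.01)
    row_a[20] = 10.0   # A prefers a late offset
    row_a[1] = 5.0
    row_b = np.full(25, 0.01)
    row_b[10] = 10.0   # B prefers an earlier one -> order violation with A@20
    m = _matrix_for(segments, 30, [row_a, row_b])
    cfg = ScoreConfig(w_template=0.0, top_k_offsets=25)
    st = optimize(segments, m, seq, cfg,
                  Constraints(order=True, connection=False))[0]
    a_off, b_off = st.assignment[0], st.assignment[1]
    assert a_off < b_off


def test_total_score_additivity_and_empty():
    model, segments = _toy_problem(seq_len=30, seg_lens=(6, 5))
    seq = TargetSequence("A" * 30)
    rng = np.random.default_rng(1)
    m = _matrix_for(segments, 30, [rng.random(25) + 0.1,
                                   rng.random(26) + 0.1])
    cfg = ScoreConfig()
    empty = AssignmentState({})
    assert total_score(empty, segments, m, seq, cfg) == 0.0
    st = AssignmentState({0: 2, 1: 14})
    sc = total_score(st, segments, m, seq, cfg)
    assert sc == pytest.approx(sum(st.breakdown.values()))
    # hand-summed: density + template + connection for this fixed state
    gap = 14 - (2 + 6)
    ok, conn = connection_feasible(segments[0].c_end, segments[1].n_end, gap)
    assert ok
    hand = (density_term(m.p(0, 2)) + density_term(m.p(1, 14)) + conn
            + cfg.w_template * (
                template_zscore(segments[0].template_seq, seq.sequence, 2)
                + template_zscore(segments[1].template_seq, seq.sequence, 14)))
    assert sc == pytest.approx(hand)


def test_infeasible_connection_rejected():
    _, segments = _toy_problem(seq_len=30, seg_lens=(6, 5), spread=200.0)
    seq = TargetSequence("A" * 30)
    m = _matrix_for(segments, 30, [np.ones(25), np.ones(26)])
    st = AssignmentState({0: 0, 1: 7})   # gap 1, ends ~177 Å apart
    assert total_score(st, segments, m, seq, ScoreConfig()) == float("-inf")
    assert not st.valid


def test_apply_assignment_mutates_types_not_backbone():
    model, seq = make_truth(20, seed=6)
    segments = extract_segments(model)
    st = AssignmentState({0: 0})
    out = apply_assignment(model, st, segments, seq)
    assert [r.name for _, r in out.residues()] == \
        [r.name for _, r in model.residues()]

    shifted = TargetSequence(seq.sequence[5:] + "AAAAA")
    out2 = apply_assignment(model, st, segments, shifted)
    for i, (_, r) in enumerate(out2.residues()):
        assert r.one_letter == shifted[i]
        assert r.assigned_pos == i
        orig = model.chains[0].residues[i]
        np.testing.assert_allclose(r.ca.pos, orig.ca.pos)
        if r.name != orig.name:
            assert all(a.name in ("N", "CA", "C", "O", "CB")
                       for a in r.atoms)

    unassigned = apply_assignment(model, AssignmentState({}), segments, seq)
    assert all(r.assigned_pos is None for _, r in unassigned.residues())
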