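"""Loop proposal, density-guided closure and the assignment iteration."""

import numpy as np
import pytest

from morphassign.assign import (AssignmentState, Constraints, ScoreConfig,
                                apply_assignment, extract_segments)
from morphassign.density import DensityMap, rasterize, residue_stats
from morphassign.loops import (CA_SKIP_MIN, CA_STEP_MAX, CA_STEP_MIN,
                               LoopConfig, build_loop, iterate_assignment,
                               merge_with_loops, propose_loop_pairs)
from morphassign.synthetic import make_map, make_truth, perturb_template


@pytest.fixture(scope="module")
def deleted_loop_case():
    """Truth with residues 31-34 deleted from the working model."""
    truth, seq = make_truth(60, seed=3)
    dmap = make_map(truth, noise_sd=0.0)
    partial = truth.copy()
    ch = partial.chains[0]
    ch.residues = ch.residues[:30] + ch.residues[34:]
    md = rasterize(partial, like=dmap)
    guide = DensityMap(dmap.values - md.values, dmap.spacing, dmap.origin)
    rho = residue_stats(dmap, partial, model_density=md).rho_mean_all
    return truth, seq, dmap, partial, guide, rho


def test_propose_pairs_rules():
    model, _ = make_truth(40, seed=1)
    ch = model.chains[0]
    ch.residues = ch.residues[:15] + ch.residues[20:]
    segs = extract_segments(model)
    assert len(segs) == 2
    d = np.linalg.norm(segs[0].c_end - segs[1].n_end)
    cfg = LoopConfig(d_close=15.0)
    if d <= 15.0:
        assert (0, 1, None) in propose_loop_pairs(segs, None, cfg)
    # far apart and unassigned: not proposed
    far_cfg = LoopConfig(d_close=d - 1.0 if d > 1 else 0.1)
    pairs = propose_loop_pairs(segs, None, far_cfg)
    assert (0, 1, None) not in pairs or d <= far_cfg.d_close
    # assigned with a small gap: proposed regardless of distance
    st = AssignmentState({0: 0, 1: 18})
    pairs2 = propose_loop_pairs(segs, st, LoopConfig(d_close=0.1))
    gap = 18 - (0 + segs[0].n)
    assert (0, 1, gap) in pairs2


def test_build_loop_span_too_long():
    d = DensityMap(np.ones((30, 30, 30)), spacing=1.0, origin=[0, 0, 0])
    cand = build_loop(np.array([5.0, 5, 5]), np.array([25.0, 5, 5]), 2,
                      d, 1.0)
    assert not cand.accepted
    assert cand.reason == "span_too_long"


def test_build_loop_zero_length_direct_link():
    d = DensityMap(np.ones((20, 20, 20)), spacing=1.0, origin=[0, 0, 0])
    a, b = np.array([8.0, 10, 10]), np.array([11.8, 10, 10])
    cand = build_loop(a, b, 0, d, 1.0, LoopConfig(f_loop=0.5))
    assert cand.accepted and cand.n_res == 0
    flat = DensityMap(np.zeros((20, 20, 20)), spacing=1.0, origin=[0, 0, 0])
    cand2 = build_loop(a, b, 0, flat, 1.0, LoopConfig(f_loop=0.5))
    assert not cand2.accepted


def test_rebuilt_loop_tracks_truth(deleted_loop_case):
    truth, _, dmap, partial, guide, rho = deleted_loop_case
    ca = [r.ca.pos for r in truth.chains[0].residues]
    rng = np.random.default_rng(3)
    cand = build_loop(ca[29], ca[34], 4, dmap, rho, LoopConfig(), rng,
                      guide=guide)
    assert cand.accepted
    dev = np.linalg.norm(cand.trace - np.array(ca[30:34]), axis=1)
    assert dev.mean() <= 1.5


def test_accepted_loop_satisfies_step_invariants(deleted_loop_case):
    truth, _, dmap, partial, guide, rho = deleted_loop_case
    ca = [r.ca.pos for r in truth.chains[0].residues]
    rng = np.random.default_rng(5)
    cand = build_loop(ca[29], ca[34], 4, dmap, rho, LoopConfig(), rng,
                      guide=guide)
    path = cand.full_path()
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    assert np.all(steps >= CA_STEP_MIN - 0.05)
    assert np.all(steps <= CA_STEP_MAX + 0.05)
    skips = np.linalg.norm(path[2:] - path[:-2], axis=1)
    assert np.all(skips >= CA_SKIP_MIN - 0.1)
    np.testing.assert_allclose(path[0], ca[29], atol=0.5)
    np.testing.assert_allclose(path[-1], ca[34], atol=0.5)


def test_loop_acceptance_monotone_in_threshold(deleted_loop_case):
    truth, _, dmap, partial, guide, rho = deleted_loop_case
    ca = [r.ca.pos for r in truth.chains[0].residues]
    accepted = []
    for f in (0.1, 0.5, 1.0, 2.0, 5.0):
        rng = np.random.default_rng(9)
        cand = build_loop(ca[29], ca[34], 4, dmap, rho,
                          LoopConfig(f_loop=f), rng, guide=guide)
        accepted.append(cand.accepted)
    # once rejection starts it never flips back as f grows
    assert accepted == sorted(accepted, reverse=True)


def test_merge_with_loops_counting(deleted_loop_case):
    truth, seq, dmap, partial, guide, rho = deleted_loop_case
    segs = extract_segments(partial)
    assert [s.n for s in segs] == [30, 26]
    state = AssignmentState({0: 0, 1: 34})
    assigned = apply_assignment(partial, state, segs, seq)

    # no accepted loops: counts unchanged, two segments remain
    merged0 = merge_with_loops(assigned.copy(), state, segs, {}, seq)
    assert merged0.n_residues == 56
    assert len(extract_segments(merged0)) == 2

    rng = np.random.default_rng(3)
    cand = build_loop(segs[0].c_end, segs[1].n_end, 4, dmap, rho,
                      LoopConfig(), rng, 0, 1, guide=guide)
    assert cand.accepted
    merged = merge_with_loops(assigned, state, segs, {(0, 1, 4): cand}, seq)
    assert merged.n_residues == 60
    merged_segs = extract_segments(merged)
    assert [s.n for s in merged_segs] == [60]
    # a loop whose length mismatches the assigned gap is not inserted
    bad = merge_with_loops(assigned, state, segs, {(0, 1, 3): cand}, seq)
    assert bad.n_residues == 56


def test_iterate_assignment_counts_non_decreasing():
    truth, seq = make_truth(80, seed=12)
    dmap = make_map(truth, noise_sd=0.0)
    tmpl = perturb_template(truth, amplitude=0.3, mutation_frac=0.3,
                            indels=((25, 4, "delete"), (55, 3, "delete")),
                            seed=13)
    final, hist = iterate_assignment(tmpl, dmap, seq, ScoreConfig(),
                                     n_iter=3, seed=2)
    assigned = [h["n_assigned"] for h in hist]
    assert all(b >= a for a, b in zip(assigned, assigned[1:]))
    assert assigned[-1] >= 70


def test_iterate_assignment_fixed_point():
    truth, seq = make_truth(40, seed=4)
    dmap = make_map(truth, noise_sd=0.0)
    final, hist = iterate_assignment(truth.copy(), dmap, seq, ScoreConfig(),
                                     n_iter=3, seed=1)
    # fully connected, correct-sequence model: everything assigned at once
    assert hist[0]["n_assigned"] == 40
    for _, r in final.residues():
        assert r.assigned_pos == r.truth_index
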