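"""Morphing: shift search, smoothing, application, regularisation."""

import numpy as np
import pytest

from morphassign.density import rasterize
from morphassign.errors import MorphAssignError
from morphassign.morph import (MorphConfig, ShiftField, apply_shifts,
                               compute_raw_shifts, local_shift, morph,
                               regularize, shift_candidates, smooth_shifts)
from morphassign.synthetic import make_map, make_truth, main_chain_rmsd


@pytest.fixture(scope="module")
def helix20():
    model, _ = make_truth(20, seed=7)
    return model


@pytest.fixture(scope="module")
def helix20_map(helix20):
    return make_map(helix20, noise_sd=0.0)


def all_keys(model):
    return [(ch.id, r.seqid) for ch, r in model.residues()]


def test_shift_candidates_capped_and_sorted():
    cand = shift_candidates(2.0, 0.25)
    norms = np.linalg.norm(cand, axis=1)
    assert norms.max() <= 2.0 + 1e-9
    assert np.all(np.diff(norms) >= -1e-12)       # sorted by norm
    np.testing.assert_allclose(cand[0], [0, 0, 0])


def test_local_shift_zero_on_self_map(helix20, helix20_map):
    cfg = MorphConfig()
    res = helix20.chains[0].residues[10]
    shift = local_shift(helix20_map, helix20, res, cfg)
    assert np.linalg.norm(shift) <= cfg.shift_search_step / 2 + 1e-9


def test_local_shift_recovers_imposed_translation(helix20, helix20_map):
    cfg = MorphConfig(shift_search_step=0.25)
    moved = helix20.copy()
    for _, r in moved.residues():
        r.translate(np.array([-0.5, 0.0, 0.0]))
    # map was built from the unmoved model: the model must shift +0.5 in x
    res = moved.chains[0].residues[10]
    shift = local_shift(helix20_map, moved, res, cfg)
    np.testing.assert_allclose(shift, [0.5, 0.0, 0.0], atol=0.25)


def test_local_shift_matches_bruteforce_lattice(helix20, helix20_map):
    """The fused search kernel equals a per-candidate exhaustive loop."""
    from morphassign.morph import (_best, _local_model_grid, _neighbourhood,
                                   correlation_at_shifts)
    cfg = MorphConfig(shift_search_step=0.5)
    rng = np.random.default_rng(11)
    cand = shift_candidates(cfg.max_shift, cfg.shift_search_step)
    for _ in range(4):
        i = int(rng.integers(2, 18))
        res = helix20.chains[0].residues[i]
        got = local_shift(helix20_map, helix20, res, cfg, polish=False)
        ca = res.ca.pos
        pos, wt, bs = _neighbourhood(helix20, ca, cfg.sphere_radius)
        idx, pts = helix20_map.grid_points_in_sphere(ca, cfg.sphere_radius)
        map_vals = helix20_map.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        local = _local_model_grid(ca, pos, wt, bs, cfg)
        # brute force: evaluate candidates one at a time
        corr = np.array([
            correlation_at_shifts(helix20_map, local, pts, map_vals,
                                  c[None, :])[0] for c in cand])
        expected = _best(cand, corr)
        np.testing.assert_allclose(got, expected)


def test_smooth_shifts_boxcar(helix20):
    model, _ = make_truth(5, seed=0)
    keys = all_keys(model)
    raw = ShiftField({k: np.array([x, 0.0, 0.0])
                      for k, x in zip(keys, [0, 0, 2, 0, 0])})
    sm = smooth_shifts(raw, 3, model)
    xs = [sm.shifts[k][0] for k in keys]
    np.testing.assert_allclose(xs, [0, 2 / 3, 2 / 3, 2 / 3, 0])
    # constant field unchanged
    const = ShiftField({k: np.ones(3) for k in keys})
    sm2 = smooth_shifts(const, 5, model)
    for k in keys:
        np.testing.assert_allclose(sm2.shifts[k], 1.0)


def test_smoothing_does_not_cross_chains():
    a, _ = make_truth(5, seed=0)
    b, _ = make_truth(5, seed=2)
    b.chains[0].id = "B"
    model = type(a)([a.chains[0], b.chains[0]])
    keys_a = [("A", r.seqid) for r in a.chains[0].residues]
    keys_b = [("B", r.seqid) for r in b.chains[0].residues]
    raw = ShiftField({**{k: np.zeros(3) for k in keys_a},
                      **{k: np.full(3, 9.0) for k in keys_b}})
    sm = smooth_shifts(raw, 3, model)
    for k in keys_a:
        np.testing.assert_allclose(sm.shifts[k], 0.0)
    for k in keys_b:
        np.testing.assert_allclose(sm.shifts[k], 9.0)


def test_apply_shifts_rigid_per_residue(helix20):
    keys = all_keys(helix20)
    zero = ShiftField({k: np.zeros(3) for k in keys})
    same = apply_shifts(helix20, zero)
    np.testing.assert_allclose(same.coords(), helix20.coords())

    uniform = ShiftField({k: np.array([1.0, 0, 0]) for k in keys})
    moved = apply_shifts(helix20, uniform)
    np.testing.assert_allclose(moved.coords(), helix20.coords() + [1, 0, 0])

    varied = ShiftField({k: np.array([0.1 * i, 0, 0])
                         for i, k in enumerate(keys)})
    out = apply_shifts(helix20, varied)
    for (_, r0), (_, r1) in zip(helix20.residues(), out.residues()):
        p0 = np.array([a.pos for a in r0.atoms])
        p1 = np.array([a.pos for a in r1.atoms])
        d0 = np.linalg.norm(p0[:, None] - p0[None], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
    # peptide C-N distance changes by construction
    r0, r1 = out.chains[0].residues[0], out.chains[0].residues[1]
    cn = np.linalg.norm(r0.atom("C").pos - r1.atom("N").pos)
    assert cn != pytest.approx(1.329, abs=1e-3)

    with pytest.raises(MorphAssignError):
        apply_shifts(helix20, ShiftField({keys[0]: np.zeros(3)}))


def test_regularize_ideal_model_fixed_point(helix20):
    out = regularize(helix20)
    d = out.coords() - helix20.coords()
    rmsd = np.sqrt((d ** 2).sum(axis=1).mean())
    assert rmsd <= 0.01


def test_regularize_restores_pulled_link(helix20):
    broken = helix20.copy()
    r9, r10 = broken.chains[0].residues[9], broken.chains[0].residues[10]
    bond = r10.atom("N").pos - r9.atom("C").pos
    pull = bond / np.linalg.norm(bond)
    for r in broken.chains[0].residues[10:]:
        r.translate(pull)
    r9, r10 = broken.chains[0].residues[9], broken.chains[0].residues[10]
    assert np.linalg.norm(r9.atom("C").pos - r10.atom("N").pos) > 2.0
    fixed = regularize(broken)
    r9, r10 = fixed.chains[0].residues[9], fixed.chains[0].residues[10]
    cn = np.linalg.norm(r9.atom("C").pos - r10.atom("N").pos)
    assert cn == pytest.approx(1.329, abs=0.1)
    # nothing should move dramatically
    d = fixed.coords() - broken.coords()
    assert np.linalg.norm(d, axis=1).max() <= 1.5


def test_regularize_large_tether_is_identity(helix20):
    broken = helix20.copy()
    for r in broken.chains[0].residues[10:]:
        r.translate(np.array([1.0, 0.0, 0.0]))
    out = regularize(broken, w_tether=1e9)
    np.testing.assert_allclose(out.coords(), broken.coords(), atol=1e-4)


def test_morph_zero_cycles_is_identity(helix20, helix20_map):
    out, diag = morph(helix20, helix20_map, MorphConfig(n_cycles=0))
    assert diag == []
    np.testing.assert_allclose(out.coords(), helix20.coords())


def test_morph_fixed_point_and_preserves_residues(helix20, helix20_map):
    out, diag = morph(helix20, helix20_map, MorphConfig(n_cycles=2))
    assert main_chain_rmsd(out, helix20) <= 0.2
    assert out.n_residues == helix20.n_residues
    assert [r.name for _, r in out.residues()] == \
        [r.name for _, r in helix20.residues()]


def test_morph_shift_cap_and_cc_monotone(helix20, helix20_map):
    from morphassign.synthetic import perturb_template
    cfg = MorphConfig(n_cycles=3)
    tmpl = perturb_template(helix20, amplitude=1.5, mutation_frac=0.0, seed=3)
    raw = compute_raw_shifts(helix20_map, tmpl, cfg)
    assert raw.norms().max() <= cfg.max_shift + 1e-9
    sm = smooth_shifts(raw, cfg.effective_window, tmpl)
    assert sm.norms().max() <= cfg.max_shift + 1e-9
    _, diag = morph(tmpl, helix20_map, cfg)
    ccs = [d["mean_cc"] for d in diag]
    assert all(b >= a - 0.02 for a, b in zip(ccs, ccs[1:]))
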