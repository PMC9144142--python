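"""Network fusion operators and the pairwise weighted-average iteration."""

import numpy as np
import pytest

import psnfuse as pf
from conftest import random_similarity


def _sim(vals, kind="similarity"):
    n = len(vals)
    return pf.SimilarityMatrix(np.asarray(vals, dtype=float), [f"P{i}" for i in range(n)], kind)


class TestRowNormalize:
    def test_rows_sum_to_one(self):
        out = pf.row_normalize(_sim([[1, 1], [2, 2]]))
        np.testing.assert_allclose(out.values, [[0.5, 0.5], [0.5, 0.5]])

    def test_idempotent_on_row_stochastic(self, rng):
        m = random_similarity(rng, 6)
        once = pf.row_normalize(m)
        twice = pf.row_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
        np.testing.assert_allclose(once.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_becomes_uniform_with_warning(self):
        m = _sim([[0, 0, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 1, 1]])
        with pytest.warns(UserWarning, match="uniform"):
            out = pf.row_normalize(m)
        np.testing.assert_allclose(out.values[0], [0.25, 0.25, 0.25, 0.25])

    def test_negative_entries_rejected(self):
        m = _sim([[0, 1], [1, 0]])
        m.values[0, 1] = -1
        with pytest.raises(ValueError):
            pf.row_normalize(m)


class TestSymmetrize:
    def test_half_sum_with_transpose(self):
        out = pf.symmetrize(_sim([[0, 1], [0, 0]]))
        np.testing.assert_allclose(out.values, [[0, 0.5], [0.5, 0]])

    def test_exact_symmetry_and_idempotence(self, rng):
        m = _sim(rng.random((5, 5)))
        once = pf.symmetrize(m)
        assert (once.values == once.values.T).all()
        np.testing.assert_array_equal(pf.symmetrize(once).values, once.values)


class TestKnnLocalize:
    def test_keeps_strongest_link_renormalized(self):
        m = _sim([[0, 0.6, 0.4], [0.6, 0, 0.3], [0.4, 0.3, 0]])
        out = pf.knn_localize(m, 1)
        np.testing.assert_allclose(out.values[0], [0, 1.0, 0])

    def test_k_equals_n_minus_one_is_offdiagonal_row_normalize(self, rng):
        m = random_similarity(rng, 5)
        out = pf.knn_localize(m, 4)
        off = m.values.copy()
        np.fill_diagonal(off, 0.0)
        expected = off / off.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_tie_at_kth_neighbor_prefers_lower_index(self):
        m = _sim([[0, 0.5, 0.5, 0.2], [0.5, 0, 0.1, 0.1], [0.5, 0.1, 0, 0.1], [0.2, 0.1, 0.1, 0]])
        out = pf.knn_localize(m, 1)
        assert out.values[0, 1] == 1.0  # tie between cols 1 and 2 -> lower index
        assert out.values[0, 2] == 0.0

    def test_kept_rows_sum_to_one_and_preserve_rank_order(self, rng):
        m = random_similarity(rng, 12)
        out = pf.knn_localize(m, 4)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        for i in range(12):
            kept = np.flatnonzero(out.values[i])
            assert len(kept) == 4
            orig_rank = np.argsort(-out.values[i, kept], kind="stable")
            new_rank = np.argsort(-m.values[i, kept], kind="stable")
            np.testing.assert_array_equal(orig_rank, new_rank)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pf.knn_localize(random_similarity(rng, 4), 4)


class TestSnfFuse:
    CFG = dict(K=2, T=1, wts=1.0, wtd=1.0)

    def test_one_step_full_weights_is_quarter_sum(self, rng):
        """With wts=wtd=1 the cross-coupling vanishes: after any T,
        MP1=S'/2 and MP2=D'/2, so FM=(S'+D')/4."""
        s, d = random_similarity(rng, 6), random_similarity(rng, 6)
        cfg = pf.FusionConfig(K=3, T=1, wts=1.0, wtd=1.0)
        fm = pf.snf_fuse(s, d, cfg)
        from psnfuse.fusion import _prepare
        _, _, s_loc, d_loc = _prepare(s, d, cfg)
        expected = (s_loc.values / 2 + d_loc.values / 2) / 2
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(fm.values, expected, atol=1e-12)

    def test_one_step_matches_hand_iteration(self, rng):
        s, d = random_similarity(rng, 5), random_similarity(rng, 5)
        cfg = pf.FusionConfig(K=2, T=1, wts=0.3, wtd=0.7)
        from psnfuse.fusion import _prepare
        s_ns, d_ns, s_loc, d_loc = _prepare(s, d, cfg)
        mp1 = (0.3 * s_loc.values + 0.7 * d_ns.values) / 2
        mp2 = (0.7 * d_loc.values + 0.3 * s_ns.values) / 2
        expected = (mp1 + mp2) / 2
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(pf.snf_fuse(s, d, cfg).values, expected, atol=1e-12)

    def test_symmetric_channels_give_equal_states(self, rng):
        m = random_similarity(rng, 6)
        cfg = pf.FusionConfig(K=3, T=5, wts=0.4, wtd=0.4)
        fm = pf.snf_fuse(m, m, cfg)
        fp = pf.snf_fixed_point(m, m, cfg)
        # identical channels and weights: the two states stay equal, so the
        # fused matrix is just that shared state
        assert fm.is_symmetric()
        assert fm.values.shape == fp.values.shape

    def test_iterated_fuse_converges_to_analytic_fixed_point(self, rng):
        s, d = random_similarity(rng, 8), random_similarity(rng, 8)
        cfg = pf.FusionConfig(K=3, T=200, wts=0.3, wtd=0.7)
        fm = pf.snf_fuse(s, d, cfg)
        fp = pf.snf_fixed_point(s, d, cfg)
        np.testing.assert_allclose(fm.values, fp.values, atol=1e-10)

    def test_nonnegative_output(self, rng):
        fm = pf.snf_fuse(random_similarity(rng, 7), random_similarity(rng, 7), pf.FusionConfig(K=3, T=10))
        assert (fm.values >= 0).all()

    def test_exchange_symmetry(self, rng):
        s, d = random_similarity(rng, 6), random_similarity(rng, 6)
        a = pf.snf_fuse(s, d, pf.FusionConfig(K=3, T=30, wts=0.2, wtd=0.6))
        b = pf.snf_fuse(d, s, pf.FusionConfig(K=3, T=30, wts=0.6, wtd=0.2))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_contraction_toward_fixed_point(self, rng):
        """Distance to the fixed point shrinks geometrically in T."""
        s, d = random_similarity(rng, 6), random_similarity(rng, 6)
        fp = pf.snf_fixed_point(s, d, pf.FusionConfig(K=3, T=1, wts=0.3, wtd=0.5))
        errs = []
        for t in (2, 6, 10, 14):
            fm = pf.snf_fuse(s, d, pf.FusionConfig(K=3, T=t, wts=0.3, wtd=0.5))
            errs.append(np.abs(fm.values - fp.values).max())
        assert all(e2 < e1 * 0.5 for e1, e2 in zip(errs, errs[1:]))

    def test_converge_mode_stops_early(self, rng):
        s, d = random_similarity(rng, 6), random_similarity(rng, 6)
        fm = pf.snf_fuse(s, d, pf.FusionConfig(K=3, T=500, mode="converge", tolerance=1e-9))
        assert fm.n_iterations < 500

    def test_index_mismatch_rejected(self, rng):
        s = random_similarity(rng, 4)
        d = pf.SimilarityMatrix(np.eye(4), ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="index"):
            pf.snf_fuse(s, d, pf.FusionConfig(K=2))


class TestFixedPoint:
    def test_full_weights_decouple(self, rng):
        s, d = random_similarity(rng, 5), random_similarity(rng, 5)
        cfg = pf.FusionConfig(K=2, T=1, wts=1.0, wtd=1.0)
        fp = pf.snf_fixed_point(s, d, cfg)
        from psnfuse.fusion import _prepare
        _, _, s_loc, d_loc = _prepare(s, d, cfg)
        expected = (s_loc.values / 2 + d_loc.values / 2) / 2
        expected = (expected + expected.T) / 2
        np.testing.assert_allclose(fp.values, expected, atol=1e-12)

    def test_scalar_recursion_limit_is_one_third(self):
        """Degenerate scalar check: S'=D'=1, wts=wtd=0.5 drives both states to
        p* = (0.25 + 0.25*0.25)/(1-0.0625) = 1/3."""
        a = b = 0.5
        sp = dp = 1.0
        p = q = 1.0
        for _ in range(200):
            p, q = (a * sp + (1 - a) * q) / 2, (b * dp + (1 - b) * p) / 2
        assert (p + q) / 2 == pytest.approx(1 / 3, abs=1e-10)

    def test_original_snf_baseline_runs(self, rng):
        s, d = random_similarity(rng, 6), random_similarity(rng, 6)
        fm = pf.original_snf(s, d, pf.FusionConfig(K=3, T=5))
        assert fm.is_symmetric()
        assert (fm.values >= 0).all()
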