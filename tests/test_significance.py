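"""Zero-inflated Weibull null, FDR, and the combinatorial overlap test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import chicflow as cf
from chicflow.significance import (OverlapTestResult, combinatorial_overlap_pvalue,
                                   fdr_qvalues, fit_ziw, overlap_pvalue_exact,
                                   ziw_pvalue, ZIWParams)


def ziw_draws(rng, n, pi, shape, scale):
    z = rng.random(n) < pi
    x = scale * rng.weibull(shape, n)
    x[z] = 0.0
    return x


class TestFitZIW:
    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(42)
        n = 100_000
        x = ziw_draws(rng, n, pi=0.6, shape=0.8, scale=2.0)
        p = fit_ziw(x, compute_se=True)
        assert p.converged
        se_pi = np.sqrt(0.6 * 0.4 / n)
        assert abs(p.pi - 0.6) <= 3 * se_pi
        assert abs(p.shape - 0.8) <= 3 * p.se_shape
        assert abs(p.scale - 2.0) <= 3 * p.se_scale

    def test_all_zero_input(self):
        p = fit_ziw(np.zeros(1000))
        assert p.pi == 1.0 and np.isnan(p.shape)

    def test_degenerate_equal_values_raise(self):
        v = np.concatenate([np.zeros(100), np.full(500, 3.0)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_ziw(v)

    def test_too_few_nonzero_raise(self):
        with pytest.raises(ValueError, match="nonzero"):
            fit_ziw(np.concatenate([np.zeros(500), np.ones(5) + np.arange(5)]))

    def test_self_consistency_refit(self):
        """Refitting data simulated from the fitted model reproduces it."""
        rng = np.random.default_rng(7)
        x = ziw_draws(rng, 50_000, pi=0.3, shape=1.4, scale=5.0)
        p1 = fit_ziw(x)
        x2 = ziw_draws(np.random.default_rng(8), 50_000, p1.pi, p1.shape, p1.scale)
        p2 = fit_ziw(x2, compute_se=True)
        assert abs(p2.shape - p1.shape) <= 4 * p2.se_shape
        assert abs(p2.scale - p1.scale) <= 4 * p2.se_scale


class TestZIWPvalue:
    def test_zero_strength_has_p_one(self):
        p = ZIWParams(pi=0.5, shape=1.0, scale=1.0)
        assert ziw_pvalue(0.0, p) == 1.0

    def test_exponential_closed_form(self):
        p = ZIWParams(pi=0.5, shape=1.0, scale=1.0)
        assert ziw_pvalue(np.log(2), p) == pytest.approx(0.25)

    def test_monotone_nonincreasing_and_limits(self):
        p = ZIWParams(pi=0.3, shape=1.7, scale=2.0)
        x = np.linspace(0.001, 50, 500)
        pv = ziw_pvalue(x, p)
        assert (np.diff(pv) <= 0).all()
        assert pv[0] == pytest.approx(1 - 0.3, rel=1e-3)
        assert pv[-1] < 1e-12

    def test_null_pvalues_superuniform(self):
        """Empirical CDF of P under the fitted null stays near/below uniform."""
        rng = np.random.default_rng(9)
        x = ziw_draws(rng, 40_000, pi=0.4, shape=1.2, scale=3.0)
        params = fit_ziw(x)
        pv = ziw_pvalue(x, params)
        grid = np.linspace(0.01, 0.99, 50)
        ecdf = np.array([(pv <= g).mean() for g in grid])
        assert (ecdf <= grid + 0.02).all()


class TestFDR:
    def test_all_ones(self):
        assert fdr_qvalues([1, 1, 1]).tolist() == [1, 1, 1]

    def test_hand_computed_bh_example(self):
        q = fdr_qvalues([0.01, 0.02, 0.03, 0.9])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])

    def test_single_p(self):
        assert fdr_qvalues([0.2]).tolist() == [0.2]

    def test_sorted_q_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        q = fdr_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.min() >= p.min()


class TestCombinatorialOverlap:
    def test_zero_overlap_is_certain(self):
        assert combinatorial_overlap_pvalue(0, (5, 5, 5), (10, 10, 10)).pvalue == 1.0

    def test_published_scale_inputs_below_1e16(self):
        res = combinatorial_overlap_pvalue(
            147, (216379, 177893, 217396), (97376960, 95608750, 92912739)
        )
        assert res.pvalue < 1e-16
        assert res.log10_pvalue < -16
        assert res.report == "P < 1e-16"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combinatorial_overlap_pvalue(6, (5, 5, 5), (10, 10, 10))
        with pytest.raises(ValueError):
            combinatorial_overlap_pvalue(1, (5, 5, 11), (10, 9, 10))

    def test_universe_order_irrelevant(self):
        a = combinatorial_overlap_pvalue(2, (5, 4, 3), (12, 10, 8))
        b = combinatorial_overlap_pvalue(2, (3, 4, 5), (8, 10, 12))
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_exact_matches_exhaustive_enumeration_small_universe(self):
        """Hypergeometric-chain oracle vs brute-force subset enumeration, N <= 8."""
        N1, N2, N3 = 5, 6, 8
        n = (3, 4, 5)
        S1 = range(N1)
        for k in (1, 2, 3):
            total = 0
            hits = 0
            for s1 in itertools.combinations(range(N1), n[0]):
                for s2 in itertools.combinations(range(N2), n[1]):
                    inter12 = set(s1) & set(s2)
                    for s3 in itertools.combinations(range(N3), n[2]):
                        total += 1
                        if len(inter12 & set(s3)) >= k:
                            hits += 1
            exact = overlap_pvalue_exact(k, n, (N1, N2, N3))
            assert exact == pytest.approx(hits / total, rel=1e-9), k

    def test_exact_matches_monte_carlo(self):
        """Without-replacement triple-sampling MC agrees with the chain."""
        rng = np.random.default_rng(1)
        n = (5, 5, 5)
        N = (10, 10, 10)
        k = 2
        reps = 200_000
        hits = 0
        for _ in range(reps):
            s1 = set(rng.choice(10, 5, replace=False))
            s2 = set(rng.choice(10, 5, replace=False))
            s3 = set(rng.choice(10, 5, replace=False))
            if len(s1 & s2 & s3) >= k:
                hits += 1
        mc = hits / reps
        exact = overlap_pvalue_exact(k, n, N)
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(exact - mc) <= 3 * se

    def test_binomial_approximates_exact_at_scale(self):
        """The binomial model converges to the exact law for large sparse universes."""
        n = (40, 50, 60)
        N = (2000, 2500, 3000)
        for k in (1, 2):
            b = combinatorial_overlap_pvalue(k, n, N).pvalue
            e = overlap_pvalue_exact(k, n, N)
            assert b == pytest.approx(e, rel=0.15)


class TestCallInteractions:
    def _normalized_pair_matrices(self, seeds, shared, private_per_lib):
        """Tiny synthetic normalized matrices with planted strong pairs."""
        import scipy.sparse as sp
        from chicflow.matrix import ContactMatrix
        from chicflow.restriction import BinGrid

        grid = BinGrid({"a": 9_000 * 120}, 9_000)
        n = grid.n_bins
        mats = []
        for li, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            dense = np.zeros((n, n))
            for j in range(3, n):
                dense[0, j] = 1.2 * rng.weibull(2.0)
            for j in shared:
                dense[0, j] = 8.0
            for j in private_per_lib[li]:
                dense[0, j] = 8.0
            cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
            cm.enriched[0] = True
            mats.append(cm)
        return mats

    def test_shared_significant_is_intersection(self):
        shared = [20, 40, 60, 80, 100]
        private = [[25, 45], [65, 85], [30, 110]]
        mats = self._normalized_pair_matrices([1, 2, 3], shared, private)
        calls = cf.call_interactions(mats, min_nonzero=50)
        sig = calls[calls.shared_significant]
        got = set(sig["bin_j"])
        assert set(shared) <= got
        for lib in private:
            assert not (set(lib) & got)

    def test_pure_null_rarely_calls(self):
        mats = self._normalized_pair_matrices([5], [], [[]])
        calls = cf.call_interactions(mats, min_nonzero=50)
        assert calls["shared_significant"].mean() <= 0.05

    def test_min_separation_excludes_short_range(self):
        mats = self._normalized_pair_matrices([1], [20], [[]])
        calls = cf.call_interactions(mats, min_nonzero=50)
        assert (np.abs(calls.bin_j - calls.bin_i) >= 2).all()
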