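"""Iterative bias correction and distance normalization."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import chicflow as cf
from chicflow.matrix import ContactMatrix
from chicflow.normalization import (compute_weights, distance_normalize,
                                    estimate_distance_template,
                                    iterative_bias_correct)
from chicflow.restriction import BinGrid

from conftest import make_matrix


def two_chrom_grid(nbins_each=10, res=9000):
    L = nbins_each * res
    return BinGrid({"a": L, "b": L}, res)


class TestWeights:
    def test_hand_enumerated_trans_weights(self):
        grid = two_chrom_grid(2)
        n = grid.n_bins  # bins: a0 a1 b0 b1
        dense = np.zeros((n, n))
        dense[0, 2] = 3  # (a0, b0)
        dense[0, 3] = 1  # (a0, b1)
        dense[1, 2] = 2  # (a1, b0)
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        st = compute_weights(cm)
        assert st.w.tolist() == [4, 2, 5, 1]
        assert st.n_populated.tolist() == [2, 1, 2, 1]
        assert st.W == 12 and st.A == 6

    def test_empty_matrix_zero_weights(self):
        grid = two_chrom_grid(3)
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix((grid.n_bins, grid.n_bins)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = compute_weights(cm)
        assert (st.w == 0).all()

    def test_cis_only_matrix_warns(self):
        grid = two_chrom_grid(3)
        dense = np.zeros((grid.n_bins, grid.n_bins))
        dense[0, 1] = 5
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        with pytest.warns(UserWarning, match="no trans contacts"):
            compute_weights(cm)


class TestBiasCorrection:
    def test_uniform_matrix_is_fixed_point(self):
        grid = two_chrom_grid(5)
        n = grid.n_bins
        dense = np.triu(np.ones((n, n)), k=1) * 4.0
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        out, st = iterative_bias_correct(cm, tol=1e-9)
        assert st.converged and st.iteration <= 2
        np.testing.assert_allclose(out.values.toarray(), dense, rtol=1e-9)

    def _planted(self, seed=0, nbins=12):
        """Counts T_ij * b_i * b_j with identical bias profile per chromosome,
        uniform trans T, structured cis T."""
        grid = two_chrom_grid(nbins)
        n = grid.n_bins
        rng = np.random.default_rng(seed)
        b_half = rng.uniform(0.5, 2.0, nbins)
        b = np.concatenate([b_half, b_half])  # equal per-chromosome bias sums
        code = grid.bin_chrom_code
        T = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                T[i, j] = 6.0 if code[i] != code[j] else 30.0 / abs(i - j)
        M = T * np.outer(b, b)
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(np.triu(M)))
        return cm, T

    def test_planted_bias_recovery(self):
        cm, T = self._planted()
        out, st = iterative_bias_correct(cm, tol=1e-10, max_iter=300)
        assert st.converged
        V = out.values.toarray()
        iu = np.triu_indices(cm.n_bins, 1)
        mask = T[iu] > 0
        ratio = V[iu][mask] / T[iu][mask]
        assert ratio.max() / ratio.min() < 1.01  # proportional within 1%
        r = np.corrcoef(V[iu][mask], T[iu][mask])[0, 1]
        assert r >= 0.99

    def test_w_hat_converges_to_unity(self):
        cm, _ = self._planted(seed=3)
        out, st = iterative_bias_correct(cm, tol=1e-6)
        assert st.converged
        assert st.max_deviation() <= 1e-6

    def test_scale_equivariance(self):
        cm, _ = self._planted(seed=4)
        out1, _ = iterative_bias_correct(cm, tol=1e-10)
        cm2 = cm.copy()
        cm2.values = cm.values * 7.0
        cm2.counts = (cm.counts * 7.0).tocsr()
        out2, _ = iterative_bias_correct(cm2, tol=1e-10)
        np.testing.assert_allclose(out2.values.toarray(), 7.0 * out1.values.toarray(),
                                   rtol=1e-8)

    def test_mass_preserved(self):
        cm, _ = self._planted(seed=5)
        before = cm.values.sum()
        out, st = iterative_bias_correct(cm, tol=1e-10)
        # mass restored over retained bins
        assert out.values.sum() == pytest.approx(before, rel=1e-9)

    def test_low_weight_bin_excluded_by_3sd_rule(self):
        # near-uniform trans weights, then one bin silenced: its zero weight
        # falls more than 3 s.d. below the mean and must be discarded
        grid = two_chrom_grid(12)
        n = grid.n_bins
        rng = np.random.default_rng(6)
        code = grid.bin_chrom_code
        dense = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if code[i] != code[j]:
                    dense[i, j] = rng.uniform(5.5, 6.5)
        kill = 0
        dense[kill, :] = 0
        dense[:, kill] = 0
        cm2 = ContactMatrix(grid=grid, counts=sp.csr_matrix(np.triu(dense)))
        out, st = iterative_bias_correct(cm2, tol=1e-8)
        assert not st.retained[kill]
        assert st.retained.sum() == n - 1

    def test_all_bins_invalid_raises(self):
        grid = two_chrom_grid(3)
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix((grid.n_bins, grid.n_bins)))
        cm.valid[:] = False
        with pytest.raises(ValueError):
            iterative_bias_correct(cm)


class TestDistanceTemplate:
    def test_long_range_exponent_recovery(self):
        d = cf.simulate_decay_contacts(400_000, 20_000_000, -0.97, 5e5, 7e6, seed=1)
        grid = BinGrid({"chrS1": 20_000_000}, 9_000)
        cm = cf.bin_contacts(d, grid)
        tpl = estimate_distance_template(cm)
        assert tpl.alpha_long == pytest.approx(-0.97, abs=0.05)

    def test_short_range_exponent_recovery(self):
        d = cf.simulate_decay_contacts(400_000, 20_000_000, -0.52, 9e3, 5e5, seed=2)
        grid = BinGrid({"chrS1": 20_000_000}, 3_000)
        cm = cf.bin_contacts(d, grid)
        tpl = estimate_distance_template(cm)
        assert tpl.alpha_short == pytest.approx(-0.52, abs=0.05)

    def test_uniform_contacts_flat_profile(self):
        d = cf.simulate_decay_contacts(200_000, 20_000_000, 0.0, 9e3, 7e6, seed=3)
        grid = BinGrid({"chrS1": 20_000_000}, 9_000)
        cm = cf.bin_contacts(d, grid)
        tpl = estimate_distance_template(cm, fit_long=(9e3, 7e6))
        assert tpl.alpha_long == pytest.approx(0.0, abs=0.05)

    def test_template_positive_and_monotone(self):
        d = cf.simulate_decay_contacts(100_000, 20_000_000, -0.8, 9e3, 7e6, seed=4)
        grid = BinGrid({"chrS1": 20_000_000}, 9_000)
        tpl = estimate_distance_template(cf.bin_contacts(d, grid))
        assert (tpl.expected > 0).all()
        assert (np.diff(tpl.expected) <= 1e-12).all()


class TestDistanceNormalize:
    def test_divides_by_expected(self):
        from chicflow.normalization import DistanceTemplate

        grid = BinGrid({"a": 90_000}, 9_000)
        dense = np.zeros((10, 10))
        dense[0, 5] = 6.0
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        tpl = DistanceTemplate(distance=np.array([9e3, 9e4]),
                               expected=np.array([2.0, 2.0]),
                               alpha_short=0.0, alpha_long=0.0)
        out = distance_normalize(cm, tpl)
        assert out.values[0, 5] == pytest.approx(3.0)

    def test_zero_coverage_interactor_attenuates_fully(self):
        from chicflow.normalization import DistanceTemplate

        grid = BinGrid({"a": 90_000}, 9_000)
        dense = np.zeros((10, 10))
        dense[0, 5] = 6.0
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        cm.enriched[0] = True
        tpl = DistanceTemplate(distance=np.array([9e3, 9e4]),
                               expected=np.array([2.0, 2.0]),
                               alpha_short=0.0, alpha_long=0.0)
        cov = np.ones(10)
        cov[5] = 0.0
        out = distance_normalize(cm, tpl, coverage=cov, lambda_cov=1.0)
        # gamma ~ eps: correction fully attenuated, value (almost) unchanged
        assert out.values[0, 5] == pytest.approx(6.0, rel=1e-4)

    def test_self_consistency_flat_after_normalization(self):
        d = cf.simulate_decay_contacts(400_000, 20_000_000, -0.97, 5e5, 7e6, seed=5)
        grid = BinGrid({"chrS1": 20_000_000}, 9_000)
        cm = cf.bin_contacts(d, grid)
        tpl = estimate_distance_template(cm)
        out = distance_normalize(cm, tpl)
        tpl2 = estimate_distance_template(out, fit_long=(6e5, 6e6))
        assert tpl2.alpha_long == pytest.approx(0.0, abs=0.05)

    def test_trans_entries_unchanged(self):
        from chicflow.normalization import DistanceTemplate

        grid = two_chrom_grid(5)
        dense = np.zeros((10, 10))
        dense[0, 7] = 4.0  # trans
        dense[0, 3] = 4.0  # cis
        cm = ContactMatrix(grid=grid, counts=sp.csr_matrix(dense))
        tpl = DistanceTemplate(distance=np.array([9e3, 9e4]),
                               expected=np.array([2.0, 2.0]),
                               alpha_short=0.0, alpha_long=0.0)
        out = distance_normalize(cm, tpl)
        assert out.values[0, 7] == 4.0
        assert out.values[0, 3] == pytest.approx(2.0)
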