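"""Enrichment factor, association/regulatory overlap tests, TF sharing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import chicflow as cf
from chicflow.restriction import BinGrid
from chicflow.stats import (association_overlap_test, enrichment_factor,
                            low_association_mask, regroup_chromatin_states,
                            regulatory_overlap_mc, tf_sharing_test)


def lib(rng, n, chrom="c", L=1_000_000):
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n)],
            "chrom1": chrom, "pos1": rng.integers(0, L, n),
            "strand1": "+", "mapq1": 60,
            "chrom2": chrom, "pos2": rng.integers(0, L, n),
            "strand2": "-", "mapq2": 60,
        }
    )


class TestEnrichment:
    def test_identical_libraries_fold_one(self):
        rng = np.random.default_rng(0)
        L = lib(rng, 5000)
        res = enrichment_factor(L, L.copy(), [("c", 0, 100_000)], seed=1)
        assert res.fold == pytest.approx(1.0, rel=0.15)

    def test_zero_on_target_reference(self):
        rng = np.random.default_rng(1)
        test = lib(rng, 500)
        ref = test.copy()
        ref["pos1"] = 900_000
        ref["pos2"] = 950_000
        with pytest.warns(UserWarning, match="no on-target"):
            res = enrichment_factor(test, ref, [("c", 0, 100_000)], seed=2)
        assert np.isinf(res.fold)

    def test_reciprocal_folds_cancel(self):
        rng = np.random.default_rng(2)
        a = lib(rng, 20_000)
        b = lib(rng, 20_000)
        # bias library b toward the target
        b.loc[: len(b) // 2, "pos1"] = rng.integers(0, 100_000, len(b) // 2 + 1)
        targets = [("c", 0, 100_000)]
        f_ab = enrichment_factor(a, b, targets, seed=3).fold
        f_ba = enrichment_factor(b, a, targets, seed=3).fold
        assert f_ab * f_ba == pytest.approx(1.0, rel=0.1)

    def test_simulator_capture_fold_recovered(self):
        """Measured enrichment matches the configured fold within 15%."""
        base = dict(
            chrom_lengths={"chrS1": 12_000_000, "chrS2": 12_000_000},
            baits=[("chrS1", 6_000_000, 6_027_000)],
            library_size=120_000, d_max=3_000_000.0, seed=31,
        )
        cfg_cap = cf.SimulationConfig(capture_fold=60.0, **base)
        fmap, _ = cf.planted_fragment_map(cfg_cap)
        captured, truth = cf.simulate_library(cfg_cap, fmap)
        cfg_ref = cf.SimulationConfig(capture_fold=1.0, **base)
        reference, _ = cf.simulate_library(cfg_ref, fmap)
        res = enrichment_factor(captured, reference, cfg_cap.baits,
                                grid=truth.grid, seed=5)
        assert res.fold == pytest.approx(60.0, rel=0.15)
        assert res.per_bin_ratio > 10


class TestAssociationOverlap:
    def test_published_counts_reproduce_fisher_p(self):
        p, odds = association_overlap_test(366, 88, 61, 23)
        assert p == pytest.approx(8.54e-3, rel=1e-3)

    def test_equal_proportions_p_one(self):
        p, _ = association_overlap_test(100, 50, 20, 10)
        assert p == 1.0

    def test_matches_hypergeometric_enumeration_oracle(self):
        """Two-sided Fisher P equals summing hypergeometric point masses no
        larger than the observed one, over all tables with the same margins."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            total = int(rng.integers(10, 50))
            overlap = int(rng.integers(1, total))
            sig = int(rng.integers(1, total))
            k = int(rng.integers(max(0, sig + overlap - total), min(sig, overlap) + 1))
            p, _ = association_overlap_test(total, overlap, sig, k)
            hg = sps.hypergeom(total, overlap, sig)
            probs = hg.pmf(np.arange(max(0, sig + overlap - total), min(sig, overlap) + 1))
            p_oracle = probs[probs <= hg.pmf(k) * (1 + 1e-9)].sum()
            assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_inconsistent_margins_raise(self):
        with pytest.raises(ValueError):
            association_overlap_test(10, 5, 4, 5)


class TestLowAssociationMask:
    def test_order_of_magnitude_rule(self):
        grid = BinGrid({"c": 90_000}, 9_000)
        assoc = pd.DataFrame(
            {"chrom": "c", "pos": [1000, 19_000, 40_000],
             "pvalue": [1e-8, 9e-8, 5e-6]}
        )
        mask = low_association_mask(assoc, [("c", 0, 90_000)], grid)
        assert mask[0] and mask[2] and not mask[4]  # 5e-6 > 10 * 1e-8

    def test_all_equal_pvalues_flag_every_snp_bin(self):
        grid = BinGrid({"c": 90_000}, 9_000)
        assoc = pd.DataFrame({"chrom": "c", "pos": [500, 30_000], "pvalue": [1e-4, 1e-4]})
        mask = low_association_mask(assoc, [("c", 0, 90_000)], grid)
        assert mask[0] and mask[3]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        grid = BinGrid({"c": 900_000}, 9_000)
        assoc = pd.DataFrame(
            {"chrom": "c", "pos": rng.integers(0, 900_000, 300),
             "pvalue": 10.0 ** -rng.uniform(2, 10, 300)}
        )
        regions = [("c", 0, 450_000), ("c", 450_000, 900_000)]
        mask = low_association_mask(assoc, regions, grid)
        brute = np.zeros(grid.n_bins, dtype=bool)
        for cs, ce in [(0, 450_000), (450_000, 900_000)]:
            sub = assoc[(assoc.pos >= cs) & (assoc.pos < ce)]
            cut = 10 * sub.pvalue.min()
            for _, row in sub[sub.pvalue <= cut].iterrows():
                brute[row.pos // 9_000] = True
        np.testing.assert_array_equal(mask, brute)

    def test_empty_region_raises(self):
        grid = BinGrid({"c": 90_000}, 9_000)
        assoc = pd.DataFrame({"chrom": "c", "pos": [500], "pvalue": [1e-4]})
        with pytest.raises(ValueError):
            low_association_mask(assoc, [("c", 50_000, 90_000)], grid)


class TestRegulatoryOverlapMC:
    def test_elements_cover_everything(self):
        universe = np.arange(200)
        res = regulatory_overlap_mc(np.arange(10), {"enh": universe}, universe,
                                    n_mc=500, seed=1)
        assert res.loc[0, "pvalue"] == 1.0

    def test_perfect_overlap_reports_bound(self):
        universe = np.arange(200)
        sig = np.arange(10)
        res = regulatory_overlap_mc(sig, {"enh": sig}, universe, n_mc=1000, seed=2)
        assert res.loc[0, "m_c"] == 0
        assert res.loc[0, "report"] == "P < 0.001"

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(5)
        universe = np.arange(1000)
        elements = rng.choice(universe, 300, replace=False)
        inside = rng.choice(elements, 45, replace=False)
        outside = rng.choice(np.setdiff1d(universe, elements), 16, replace=False)
        sig = np.concatenate([inside, outside])  # ~74% overlap vs 30% expected
        res = regulatory_overlap_mc(sig, {"enh": elements}, universe,
                                    n_mc=10_000, seed=3)
        assert res.loc[0, "pvalue"] < 0.01

    def test_seed_stability_within_binomial_error(self):
        rng = np.random.default_rng(6)
        universe = np.arange(500)
        elements = rng.choice(universe, 200, replace=False)
        sig = np.concatenate([rng.choice(elements, 30, replace=False),
                              rng.choice(np.setdiff1d(universe, elements), 31, replace=False)])
        ps = [
            regulatory_overlap_mc(sig, {"e": elements}, universe, n_mc=2000,
                                  seed=s).loc[0, "pvalue"]
            for s in range(10)
        ]
        p = np.mean(ps)
        assert np.std(ps) <= 3 * np.sqrt(p * (1 - p) / 2000) + 1e-9


class TestTFSharing:
    def test_no_peaks_degenerate(self):
        calls = pd.DataFrame({"bin_i": [0, 1], "bin_j": [10, 11]})
        out = tf_sharing_test(calls, {}, 20, {}, seed=1)
        assert out["degenerate"] and out["pvalue"] == 1.0

    def test_planted_sharing_detected(self):
        rng = np.random.default_rng(7)
        n_bins = 400
        n_pairs = 147
        anchors = rng.choice(np.arange(0, 50), n_pairs)
        interactors = rng.choice(np.arange(100, 400), n_pairs, replace=False)
        calls = pd.DataFrame({"bin_i": anchors, "bin_j": interactors})
        # each real pair shares one specific TF; permuted pairs usually mismatch
        tf_bins = {
            f"tf{t}": np.unique(np.concatenate(
                [anchors[np.arange(n_pairs) % 3 == t],
                 interactors[np.arange(n_pairs) % 3 == t]]
            ))
            for t in range(3)
        }
        region = {int(b): 0 for b in range(0, 50)}  # all anchors in one test region
        out = tf_sharing_test(calls, tf_bins, n_bins, region, seed=8)
        assert out["pvalue"] < 1e-3
        assert out["real_counts"].mean() > out["control_counts"].mean()

    def test_null_calibration_rejection_rate(self):
        """Real pairs drawn like controls: rejections near the nominal level."""
        rng = np.random.default_rng(9)
        n_bins = 300
        tf_bins = {f"tf{t}": rng.choice(n_bins, 60, replace=False) for t in range(5)}
        rejections = 0
        reps = 60
        for s in range(reps):
            r = np.random.default_rng(100 + s)
            calls = pd.DataFrame(
                {"bin_i": r.choice(50, 60), "bin_j": r.choice(np.arange(60, 300), 60)}
            )
            out = tf_sharing_test(calls, tf_bins, n_bins, {}, seed=s)
            if out["pvalue"] < 0.05:
                rejections += 1
        assert rejections / reps <= 0.12


class TestRegroupStates:
    def test_adjacent_same_class_merged(self):
        seg = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 200], "end": [200, 400],
             "state": ["E1", "E2"]}
        )
        out = regroup_chromatin_states(seg, {"E1": "enhancer", "E2": "enhancer"})
        assert len(out) == 1 and out.loc[0, "end"] == 400

    def test_unmapped_label_raises_listing_offenders(self):
        seg = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10], "state": ["X9"]})
        with pytest.raises(ValueError, match="X9"):
            regroup_chromatin_states(seg, {"E1": "enhancer"})

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        starts = np.arange(0, 2000, 200)
        states = rng.choice(["P", "E", "T", "O"], len(starts))
        seg = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 200,
                            "state": states})
        mapping = {"P": "promoter", "E": "enhancer", "T": "transcribed", "O": "other"}
        a = regroup_chromatin_states(seg, mapping)
        b = regroup_chromatin_states(seg.sample(frac=1, random_state=1), mapping)
        pd.testing.assert_frame_equal(a, b)
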