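"""Downstream enrichment and overlap statistics for capture Hi-C call sets.

Covers the capture enrichment factor (on-target read-fraction ratio between a
size-matched captured and uncaptured library), the Fisher test for overlap of
significant bins with strong association signals, a Monte Carlo test for
overlap with regulatory chromatin segments, the shared-transcription-factor
permutation test, and regrouping of chromatin-segmentation states to a
simplified four-class scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .restriction import BinGrid

__all__ = [
    "EnrichmentResult",
    "enrichment_factor",
    "association_overlap_test",
    "low_association_mask",
    "regulatory_overlap_mc",
    "tf_sharing_test",
    "regroup_chromatin_states",
]


def _interval_trees(intervals: Iterable[Tuple[str, int, int]]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _on_target(ditags: pd.DataFrame, trees: Mapping[str, IntervalTree]) -> np.ndarray:
    """A ditag is on-target when either end falls inside a target interval."""
    hit = np.zeros(len(ditags), dtype=bool)
    for ccol, pcol in (("chrom1", "pos1"), ("chrom2", "pos2")):
        for chrom, tree in trees.items():
            mask = (ditags[ccol] == chrom).to_numpy()
            if mask.any():
                pos = ditags.loc[mask, pcol].to_numpy()
                hit[mask] |= np.array([bool(tree[int(p)]) for p in pos])
    return hit


@dataclass
class EnrichmentResult:
    fold: float                 # on-target fraction(test) / on-target fraction(ref)
    test_fraction: float
    reference_fraction: float
    subsample_size: int
    mean_on_target_per_bin: float = np.nan
    mean_off_target_per_bin: float = np.nan
    per_bin_ratio: float = np.nan


def enrichment_factor(
    test: pd.DataFrame,
    reference: pd.DataFrame,
    targets: Iterable[Tuple[str, int, int]],
    subsample_size: int | None = None,
    grid: BinGrid | None = None,
    seed: int | None = None,
) -> EnrichmentResult:
    """Capture enrichment: on-target read-fraction ratio on size-matched libraries.

    Both libraries are subsampled (seeded, uniform) to the same raw size before
    measuring, mirroring the requirement that test and reference be size
    matched.  A reference with zero on-target reads yields an inf sentinel
    with a warning rather than a crash.  With a ``grid``, the mean per-bin
    on-target vs off-target read count ratio of the test library is reported
    as a complementary enrichment estimate.
    """
    if len(test) == 0 or len(reference) == 0:
        raise ValueError("both libraries must be non-empty")
    if subsample_size is None:
        subsample_size = min(len(test), len(reference))
    if subsample_size > min(len(test), len(reference)):
        raise ValueError("subsample_size exceeds a library size")
    rng = np.random.default_rng(seed)
    t = test.iloc[rng.choice(len(test), subsample_size, replace=False)]
    r = reference.iloc[rng.choice(len(reference), subsample_size, replace=False)]
    trees = _interval_trees(targets)
    t_frac = float(_on_target(t, trees).mean())
    r_frac = float(_on_target(r, trees).mean())
    if r_frac == 0.0:
        warnings.warn("reference library has no on-target reads; fold is infinite",
                      stacklevel=2)
        fold = np.inf if t_frac > 0 else np.nan
    else:
        fold = t_frac / r_frac
    result = EnrichmentResult(
        fold=fold, test_fraction=t_frac, reference_fraction=r_frac,
        subsample_size=subsample_size,
    )
    if grid is not None:
        counts = np.zeros(grid.n_bins)
        for ccol, pcol in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom in grid.chroms:
                m = (t[ccol] == chrom).to_numpy()
                if m.any():
                    np.add.at(counts, grid.bin_index(chrom, t.loc[m, pcol].to_numpy()), 1)
        on_bins = np.zeros(grid.n_bins, dtype=bool)
        for chrom, tree in trees.items():
            if chrom not in grid.chrom_lengths:
                continue
            for iv in tree:
                b0 = grid.offsets[chrom] + iv.begin // grid.resolution
                b1 = grid.offsets[chrom] + (iv.end - 1) // grid.resolution
                on_bins[b0 : b1 + 1] = True
        result.mean_on_target_per_bin = float(counts[on_bins].mean()) if on_bins.any() else np.nan
        result.mean_off_target_per_bin = float(counts[~on_bins].mean()) if (~on_bins).any() else np.nan
        if result.mean_off_target_per_bin:
            result.per_bin_ratio = result.mean_on_target_per_bin / result.mean_off_target_per_bin
    return result


def association_overlap_test(
    all_bins: int, overlap_bins: int, sig_bins: int, sig_overlap_bins: int
) -> Tuple[float, float]:
    """Two-sided Fisher exact test: do significant bins overlap strong
    association signals more often than the remaining bins?

    Returns (p_value, odds_ratio) for the 2x2 table
    [[sig & overlap, sig & ~overlap], [~sig & overlap, ~sig & ~overlap]].
    """
    if sig_overlap_bins > min(sig_bins, overlap_bins):
        raise ValueError("overlap of the two sets exceeds a set size")
    if sig_bins > all_bins or overlap_bins > all_bins:
        raise ValueError("subset larger than the universe")
    a = sig_overlap_bins
    b = sig_bins - sig_overlap_bins
    c = overlap_bins - sig_overlap_bins
    d = all_bins - sig_bins - c
    if d < 0:
        raise ValueError("inconsistent contingency margins")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), float(odds)


def low_association_mask(
    assoc: pd.DataFrame,
    regions: Sequence[Tuple[str, int, int]],
    grid: BinGrid,
    order_of_magnitude: float = 10.0,
) -> np.ndarray:
    """Flag bins containing a SNP within one order of magnitude of its
    region's lowest association P value.

    ``assoc`` has columns (chrom, pos, pvalue).  Each region must contain at
    least one SNP; a bin is flagged iff it holds >=1 SNP with
    P <= order_of_magnitude * min(P of the region).
    """
    mask = np.zeros(grid.n_bins, dtype=bool)
    for chrom, start, end in regions:
        sel = (
            (assoc["chrom"] == chrom)
            & (assoc["pos"] >= start)
            & (assoc["pos"] < end)
        )
        if not sel.any():
            raise ValueError(f"region {chrom}:{start}-{end} contains no SNPs")
        sub = assoc[sel]
        cutoff = order_of_magnitude * sub["pvalue"].min()
        qual = sub[sub["pvalue"] <= cutoff]
        bins = grid.bin_index(chrom, qual["pos"].to_numpy())
        mask[bins] = True
    return mask


def regulatory_overlap_mc(
    sig_bins: np.ndarray,
    element_bins: Mapping[str, np.ndarray],
    universe: np.ndarray,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte Carlo overlap test of significant bins with regulatory elements.

    For each element class, the observed proportion of significant bins
    overlapping the class is compared with the proportions in ``n_mc`` random
    same-size samples of bins drawn (without replacement within a draw) from
    the genome-wide valid-bin ``universe``.  P = m_c / n_mc with m_c = number
    of samples reaching the observed proportion; m_c = 0 is reported as
    "<1/n_mc".
    """
    rng = np.random.default_rng(seed)
    sig_bins = np.asarray(sig_bins)
    k = len(sig_bins)
    if k == 0:
        raise ValueError("no significant bins supplied")
    samples = np.empty((n_mc, k), dtype=np.int64)
    for s in range(n_mc):
        samples[s] = rng.choice(universe, size=k, replace=False)
    rows = []
    for cls, bins in element_bins.items():
        member = np.zeros(int(universe.max()) + 2, dtype=bool)
        member[np.asarray(bins, dtype=np.int64)] = True
        observed = float(member[sig_bins].mean())
        null_props = member[samples].mean(axis=1)
        m_c = int((null_props >= observed).sum())
        p = m_c / n_mc
        rows.append(
            {
                "class": cls,
                "observed_proportion": observed,
                "null_mean_proportion": float(null_props.mean()),
                "m_c": m_c,
                "n_mc": n_mc,
                "pvalue": p,
                "report": f"P < {1.0 / n_mc:g}" if m_c == 0 else f"P = {p:g}",
            }
        )
    return pd.DataFrame(rows)


def _count_shared_tfs(
    pairs: Sequence[Tuple[int, int]], tf_bins: Mapping[str, np.ndarray], n_bins: int
) -> np.ndarray:
    """Per pair, the number of TFs with >=1 peak in BOTH bins."""
    marks = {}
    for tf, bins in tf_bins.items():
        m = np.zeros(n_bins, dtype=bool)
        m[np.asarray(bins, dtype=np.int64)] = True
        marks[tf] = m
    counts = np.zeros(len(pairs), dtype=int)
    for idx, (i, j) in enumerate(pairs):
        counts[idx] = sum(1 for m in marks.values() if m[i] and m[j])
    return counts


def tf_sharing_test(
    calls: pd.DataFrame,
    tf_bins: Mapping[str, np.ndarray],
    n_bins: int,
    test_region_of_bin: Mapping[int, int],
    n_pairs: int | None = None,
    seed: int | None = None,
    max_resample: int = 1000,
) -> Dict[str, object]:
    """Do interacting pairs share TF binding more than permuted controls?

    ``calls`` needs columns (bin_i, bin_j); ``test_region_of_bin`` maps bin ->
    test-region id (capture bins only).  Controls permute the interactor bins
    across calls, rejecting control pairs whose two bins fall in the same test
    region; ``n_pairs`` controls default to the number of real pairs.  The
    real and control shared-TF counts are compared with a two-sided
    Mann-Whitney U test.  With no TF peaks anywhere the test is degenerate
    (all counts zero) and P = 1 is returned with a flag.
    """
    rng = np.random.default_rng(seed)
    real_pairs = list(zip(calls["bin_i"].astype(int), calls["bin_j"].astype(int)))
    if n_pairs is None:
        n_pairs = len(real_pairs)
    real_counts = _count_shared_tfs(real_pairs, tf_bins, n_bins)

    anchors = calls["bin_i"].to_numpy(dtype=int)
    interactors = calls["bin_j"].to_numpy(dtype=int)
    control_pairs: List[Tuple[int, int]] = []
    for _ in range(max_resample):
        perm = rng.permutation(interactors)
        for a, b in zip(anchors, perm):
            ra = test_region_of_bin.get(int(a))
            rb = test_region_of_bin.get(int(b))
            if ra is not None and rb is not None and ra == rb:
                continue  # same test region: excluded from the control set
            control_pairs.append((int(a), int(b)))
            if len(control_pairs) >= n_pairs:
                break
        if len(control_pairs) >= n_pairs:
            break
    control_counts = _count_shared_tfs(control_pairs, tf_bins, n_bins)

    degenerate = real_counts.max(initial=0) == 0 and control_counts.max(initial=0) == 0
    if degenerate:
        p = 1.0
        u = np.nan
    else:
        u, p = sps.mannwhitneyu(real_counts, control_counts, alternative="two-sided")
    return {
        "real_counts": real_counts,
        "control_counts": control_counts,
        "U": float(u) if np.isfinite(np.asarray(u, dtype=float)) else np.nan,
        "pvalue": float(p),
        "degenerate": bool(degenerate),
        "n_real": len(real_counts),
        "n_control": len(control_counts),
    }


def regroup_chromatin_states(
    segmentation: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Regroup a chromatin segmentation to a simplified class scheme.

    ``segmentation`` has columns (chrom, start, end, state); every input state
    must appear in ``mapping`` (e.g. to {promoter, enhancer, transcribed,
    other}); adjacent intervals of equal class are merged.  Output is sorted
    by (chrom, start) and independent of input order.
    """
    unknown = sorted(set(segmentation["state"]) - set(mapping))
    if unknown:
        raise ValueError(f"unmapped chromatin states: {unknown}")
    df = segmentation.copy()
    df["class"] = df["state"].map(mapping)
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur = None
        for _, r in sub.iterrows():
            if cur is not None and r["class"] == cur[3] and r["start"] <= cur[2]:
                cur[2] = max(cur[2], r["end"])
            else:
                if cur is not None:
                    rows.append(tuple(cur))
                cur = [chrom, int(r["start"]), int(r["end"]), r["class"]]
        if cur is not None:
            rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
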