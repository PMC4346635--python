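"""Ditag assembly and filtering for bona fide Hi-C contacts.

A ditag is one chimeric ligation product: two single-end alignments sharing a
read id.  Raw ditag streams contain experimental background — self-ligated,
non-digested and circularized fragments, and reads too far from any
restriction site to be a plausible ligation junction — which is removed by
orientation/distance rules against the fragment map, after mapping-quality
and PCR-duplicate filtering.

The per-category bookkeeping (FilterReport) is exact: categories are disjoint
and sum to the input pair count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .restriction import FragmentMap

__all__ = [
    "FilterReport",
    "assemble_ditags",
    "remove_duplicates",
    "classify_artifact",
    "classify_artifacts",
    "filter_bona_fide",
    "DITAG_COLUMNS",
    "DEFAULT_MAPQ_MIN",
    "DEFAULT_MAX_SITE_DISTANCE",
]

DITAG_COLUMNS = [
    "read_id",
    "chrom1", "pos1", "strand1", "mapq1",
    "chrom2", "pos2", "strand2", "mapq2",
]

DEFAULT_MAPQ_MIN = 30          # uniquely-aligned threshold: MAPQ>30, strict
DEFAULT_MAX_SITE_DISTANCE = 800  # bp; sonication peaks at ~500 bp


@dataclass
class FilterReport:
    """Disjoint ditag accounting; categories sum to the input pair count."""

    input_pairs: int = 0
    sub_mapq: int = 0
    singleton: int = 0
    duplicates: int = 0
    self_ligation: int = 0
    non_digested: int = 0
    circularized: int = 0
    no_site: int = 0
    valid: int = 0

    def total_classified(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self) if f.name != "input_pairs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.name, getattr(self, f.name)) for f in fields(self)],
            columns=["category", "count"],
        )


def _canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    """Order the two ends of each ditag by (chrom, pos), lower end first."""
    key1 = list(zip(df["chrom1"], df["pos1"]))
    key2 = list(zip(df["chrom2"], df["pos2"]))
    swap = np.array([k1 > k2 for k1, k2 in zip(key1, key2)])
    if swap.any():
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                     ("strand1", "strand2"), ("mapq1", "mapq2")):
            tmp = df.loc[swap, a].to_numpy()
            df.loc[swap, a] = df.loc[swap, b].to_numpy()
            df.loc[swap, b] = tmp
    return df


def assemble_ditags(
    alignments: pd.DataFrame, mapq_min: int = DEFAULT_MAPQ_MIN
) -> Tuple[pd.DataFrame, FilterReport]:
    """Pair per-end alignment records into ditags and apply the MAPQ filter.

    ``alignments`` has columns (read_id, chrom, pos, strand, mapq), one row per
    aligned end.  Pairs are retained only when BOTH ends exceed ``mapq_min``
    strictly; read ids with a single aligned end are dropped as singletons.
    More than two ends for one read id is malformed input.
    """
    report = FilterReport()
    counts = alignments["read_id"].value_counts()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise ValueError(f"read id {bad!r} has more than two aligned ends")
    report.singleton = int((counts == 1).sum())
    paired_ids = counts[counts == 2].index
    sub = alignments[alignments["read_id"].isin(paired_ids)].sort_values(
        ["read_id"], kind="stable"
    )
    report.input_pairs = int(len(counts))
    first = sub.iloc[0::2].reset_index(drop=True)
    second = sub.iloc[1::2].reset_index(drop=True)
    ditags = pd.DataFrame(
        {
            "read_id": first["read_id"],
            "chrom1": first["chrom"].to_numpy(),
            "pos1": first["pos"].to_numpy(),
            "strand1": first["strand"].to_numpy(),
            "mapq1": first["mapq"].to_numpy(),
            "chrom2": second["chrom"].to_numpy(),
            "pos2": second["pos"].to_numpy(),
            "strand2": second["strand"].to_numpy(),
            "mapq2": second["mapq"].to_numpy(),
        }
    )
    keep = (ditags["mapq1"] > mapq_min) & (ditags["mapq2"] > mapq_min)
    report.sub_mapq = int((~keep).sum())
    ditags = _canonical_order(ditags[keep].reset_index(drop=True))
    return ditags, report


def remove_duplicates(ditags: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Collapse PCR duplicates: identical (chrom, pos, strand) on both ends.

    Ditags must be canonically ordered so that end-swapped copies compare
    equal.  The first occurrence survives; input order is preserved.
    """
    key_cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    dup = ditags.duplicated(subset=key_cols, keep="first")
    return ditags[~dup].reset_index(drop=True), int(dup.sum())


def _classify_arrays(
    same_chrom: np.ndarray,
    frag1: np.ndarray,
    frag2: np.ndarray,
    strand1: np.ndarray,
    strand2: np.ndarray,
    dist1: np.ndarray,
    dist2: np.ndarray,
    max_site_distance: float,
) -> np.ndarray:
    """Vectorized artifact rule table; ends assumed canonically ordered.

    With end 1 upstream of end 2: inward = (+,-), outward = (-,+).
    same fragment + inward  -> non_digested (the junction was never cut)
    same fragment + outward -> self_ligation (fragment circularized on itself)
    adjacent fragments + outward -> circularized (re-ligation loop)
    either end > max_site_distance from any cut -> no_site
    everything else -> valid
    """
    cat = np.full(len(frag1), "valid", dtype=object)
    inward = (strand1 == "+") & (strand2 == "-")
    outward = (strand1 == "-") & (strand2 == "+")
    same_frag = same_chrom & (frag1 == frag2)
    adjacent = same_chrom & (np.abs(frag1 - frag2) == 1)
    cat[same_frag & inward] = "non_digested"
    cat[same_frag & outward] = "self_ligation"
    cat[adjacent & outward] = "circularized"
    far = (dist1 > max_site_distance) | (dist2 > max_site_distance)
    cat[far] = "no_site"  # distance rule dominates: no junction is plausible at all
    return cat


def classify_artifact(
    ditag: Dict, fmap: FragmentMap, max_site_distance: float = DEFAULT_MAX_SITE_DISTANCE
) -> str:
    """Classify a single ditag (mapping with the DITAG_COLUMNS fields)."""
    df = pd.DataFrame([ditag])
    return classify_artifacts(_canonical_order(df), fmap, max_site_distance)[0]


def classify_artifacts(
    ditags: pd.DataFrame, fmap: FragmentMap, max_site_distance: float = DEFAULT_MAX_SITE_DISTANCE
) -> np.ndarray:
    """Vectorized artifact classification of a canonically ordered ditag table."""
    n = len(ditags)
    frag1 = np.zeros(n, dtype=np.int64)
    frag2 = np.zeros(n, dtype=np.int64)
    dist1 = np.zeros(n)
    dist2 = np.zeros(n)
    for chrom in pd.unique(pd.concat([ditags["chrom1"], ditags["chrom2"]])):
        for fi, (ccol, pcol, darr, farr) in enumerate(
            [("chrom1", "pos1", dist1, frag1), ("chrom2", "pos2", dist2, frag2)]
        ):
            mask = (ditags[ccol] == chrom).to_numpy()
            if mask.any():
                pos = ditags.loc[mask, pcol].to_numpy()
                darr[mask] = fmap.site_distance(chrom, pos)
                farr[mask] = fmap.fragment_index(chrom, pos)
    same_chrom = (ditags["chrom1"] == ditags["chrom2"]).to_numpy()
    return _classify_arrays(
        same_chrom,
        frag1,
        frag2,
        ditags["strand1"].to_numpy(),
        ditags["strand2"].to_numpy(),
        dist1,
        dist2,
        max_site_distance,
    )


def filter_bona_fide(
    ditags: pd.DataFrame,
    fmap: FragmentMap,
    max_site_distance: float = DEFAULT_MAX_SITE_DISTANCE,
    report: FilterReport | None = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Remove duplicates and experimental-background ditags.

    Returns the valid ditag table and a FilterReport whose categories sum to
    the input count.  A ``report`` carried over from assembly is extended in
    place so the totals reconcile across the whole pipeline.
    """
    if report is None:
        report = FilterReport(input_pairs=len(ditags))
    if len(ditags) == 0:
        return ditags.copy(), report
    deduped, ndup = remove_duplicates(_canonical_order(ditags))
    report.duplicates += ndup
    cats = classify_artifacts(deduped, fmap, max_site_distance)
    for name in ("self_ligation", "non_digested", "circularized", "no_site", "valid"):
        setattr(report, name, getattr(report, name) + int((cats == name).sum()))
    return deduped[cats == "valid"].reset_index(drop=True), report
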