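"""Binned contact matrices with capture-enrichment classes and valid-bin filter.

The genome-wide contact matrix M_ij counts ditags between bins i and j of a
fixed-resolution grid.  Storage is sparse upper-triangular (i <= j) with
symmetric read semantics.  Each bin carries flags: ``enriched`` (overlaps a
capture bait), ``valid`` (contains at least one restriction site and has mean
mapability strictly above 0.5) — only valid bins of the E–E and E–N classes
enter downstream interaction analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .restriction import BinGrid, FragmentMap, annotate_bins

__all__ = [
    "ContactMatrix",
    "bin_contacts",
    "mark_enriched_bins",
    "classify_pair",
    "filter_valid_bins",
    "window_views",
    "DEFAULT_MAPABILITY_MIN",
    "DEFAULT_WINDOW",
]

DEFAULT_MAPABILITY_MIN = 0.5
DEFAULT_WINDOW = 10_000_000  # 10 Mb moving window


@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact matrix plus per-bin annotation.

    ``counts`` stores the upper triangle (i <= j, diagonal included); reads
    through :meth:`symmetric` materialize full symmetry.  ``values`` mirrors
    ``counts`` as floats and is what normalization updates; ``counts`` always
    keeps the raw integers.
    """

    grid: BinGrid
    counts: sp.csr_matrix
    enriched: np.ndarray = field(default=None)
    valid: np.ndarray = field(default=None)
    site_count: np.ndarray = field(default=None)
    mapability: np.ndarray = field(default=None)
    values: sp.csr_matrix = field(default=None)

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        if self.enriched is None:
            self.enriched = np.zeros(n, dtype=bool)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        if self.site_count is None:
            self.site_count = np.ones(n, dtype=np.int64)
        if self.mapability is None:
            self.mapability = np.ones(n)
        if self.values is None:
            self.values = self.counts.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    def mass(self) -> float:
        """Total matrix mass = number of binned ditags (upper triangle sum)."""
        return float(self.counts.sum())

    def symmetric(self, values: bool = True) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal not double-counted)."""
        m = self.values if values else self.counts
        d = sp.diags(m.diagonal())
        return m + m.T - d

    def coo(self, values: bool = True) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, data) of the stored upper triangle."""
        m = (self.values if values else self.counts).tocoo()
        return m.row, m.col, m.data

    def is_trans(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        code = self.grid.bin_chrom_code
        return code[rows] != code[cols]

    def pair_class(self, rows, cols) -> np.ndarray:
        e = self.enriched
        ne = e[rows].astype(int) + e[cols].astype(int)
        return np.array(["N-N", "E-N", "E-E"], dtype=object)[ne]

    def bin_table(self) -> pd.DataFrame:
        locs = [self.grid.bin_location(i) for i in range(self.n_bins)]
        return pd.DataFrame(
            {
                "chrom": [l[0] for l in locs],
                "start": [l[1] for l in locs],
                "end": [l[2] for l in locs],
                "enriched": self.enriched,
                "valid": self.valid,
                "site_count": self.site_count,
                "mapability": self.mapability,
            }
        )

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            grid=self.grid,
            counts=self.counts.copy(),
            enriched=self.enriched.copy(),
            valid=self.valid.copy(),
            site_count=self.site_count.copy(),
            mapability=self.mapability.copy(),
            values=self.values.copy(),
        )

    def to_coo_tsv(self, path) -> None:
        """Raw counts and current (normalized) values, one row per entry."""
        r, c, v = self.coo(values=True)
        raw = np.asarray(self.counts.tocsr()[r, c]).ravel()
        pd.DataFrame({"bin_i": r, "bin_j": c, "count": raw, "value": v}).to_csv(
            path, sep="\t", index=False
        )


def bin_contacts(
    ditags: pd.DataFrame,
    grid: BinGrid,
    fmap: FragmentMap | None = None,
    mapability: Mapping | None = None,
) -> ContactMatrix:
    """Accumulate valid ditags into an upper-triangular contact matrix.

    Each ditag increments exactly one entry (i, j) with i <= j; both ends in
    one bin increment the diagonal.  Per-bin site counts / mapability are
    annotated when a fragment map is supplied.
    """
    n = grid.n_bins
    if len(ditags):
        i = np.empty(len(ditags), dtype=np.int64)
        j = np.empty(len(ditags), dtype=np.int64)
        for chrom in grid.chroms:
            m1 = (ditags["chrom1"] == chrom).to_numpy()
            m2 = (ditags["chrom2"] == chrom).to_numpy()
            if m1.any():
                i[m1] = grid.bin_index(chrom, ditags.loc[m1, "pos1"].to_numpy())
            if m2.any():
                j[m2] = grid.bin_index(chrom, ditags.loc[m2, "pos2"].to_numpy())
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        counts = sp.coo_matrix(
            (np.ones(len(lo)), (lo, hi)), shape=(n, n)
        ).tocsr()
    else:
        counts = sp.csr_matrix((n, n))
    cm = ContactMatrix(grid=grid, counts=counts)
    if fmap is not None:
        cm.site_count, cm.mapability = annotate_bins(grid, fmap, mapability)
    return cm


def mark_enriched_bins(
    grid: BinGrid, baits: Iterable[Tuple[str, int, int]]
) -> np.ndarray:
    """Per-bin capture flag: enriched iff the bin overlaps >=1 bait by >=1 bp."""
    flags = np.zeros(grid.n_bins, dtype=bool)
    res = grid.resolution
    for chrom, start, end in baits:
        if chrom not in grid.chrom_lengths or end <= start:
            continue
        b0 = grid.offsets[chrom] + start // res
        b1 = grid.offsets[chrom] + (end - 1) // res
        last = grid.offsets[chrom] + grid.n_bins_per_chrom[chrom] - 1
        flags[b0 : min(b1, last) + 1] = True
    return flags


def classify_pair(i: int, j: int, enriched: np.ndarray) -> str:
    """Capture class of a bin pair: E-E, E-N or N-N (symmetric in i, j)."""
    n = int(enriched[i]) + int(enriched[j])
    return ("N-N", "E-N", "E-E")[n]


def filter_valid_bins(
    cm: ContactMatrix, mapability_min: float = DEFAULT_MAPABILITY_MIN
) -> ContactMatrix:
    """Mark bins lacking restriction sites or with mean mapability <= 0.5 invalid.

    Rows/columns of invalid bins are zeroed out of ``values`` so they cannot
    contribute downstream; raw ``counts`` are left intact for bookkeeping.
    Idempotent.
    """
    out = cm.copy()
    out.valid = (cm.site_count > 0) & (cm.mapability > mapability_min) & cm.valid
    bad = ~out.valid
    if bad.any():
        mask = sp.diags((~bad).astype(float))
        out.values = (mask @ out.values @ mask).tocsr()
        out.values.eliminate_zeros()
    return out


def window_views(
    cm: ContactMatrix, window: int = DEFAULT_WINDOW
) -> Iterator[Tuple[str, np.ndarray]]:
    """Tile each chromosome's bins into consecutive windows of ~``window`` bases.

    Windows partition every chromosome's bin range, so each intra-chromosomal
    entry whose both bins fall in one window is covered exactly once; the per-
    chromosome tiling uses balanced (ceiling-split) window sizes.
    """
    if window < cm.grid.resolution:
        raise ValueError("window smaller than one bin")
    for chrom in cm.grid.chroms:
        bins = cm.grid.chrom_bins(chrom)
        L = cm.grid.chrom_lengths[chrom]
        n_win = max(1, int(np.ceil(L / window)))
        for part in np.array_split(bins, n_win):
            if len(part):
                yield chrom, part
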