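"""In-silico restriction digestion and genomic bin annotation.

A Hi-C experiment is anchored on the restriction-fragment structure of the
genome: ligation junctions form at cut sites, artifact classes are defined by
fragment geometry, and bins without a cut site can never receive a bona fide
contact.  This module digests a genome with a restriction enzyme (HindIII,
``A^AGCTT``, by default), exposes the fragment coordinate system, and
annotates fixed-width bins with cut-site counts and mean mapability.

All coordinates are 0-based, half-open.  Conversion to 1-based conventions
happens only at serialization boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "FragmentMap",
    "BinGrid",
    "digest_genome",
    "nearest_site_distance",
    "annotate_bins",
    "HINDIII_PATTERN",
    "HINDIII_CUT_OFFSET",
]

HINDIII_PATTERN = "AAGCTT"
#: HindIII cleaves A^AGCTT, one base into the recognition site.
HINDIII_CUT_OFFSET = 1


def _find_occurrences(seq: str, pattern: str) -> np.ndarray:
    """All (possibly overlapping) start positions of ``pattern`` in ``seq``."""
    hits = []
    start = seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)  # step 1: overlapping hits allowed
    return np.asarray(hits, dtype=np.int64)


@dataclass
class FragmentMap:
    """Restriction cut positions and derived fragments per chromosome.

    ``cuts[chrom]`` is a strictly increasing array of cut coordinates.  The
    fragments of a chromosome of length L are the half-open intervals between
    consecutive cuts, padded with 0 and L, and therefore tile [0, L) exactly.
    """

    chrom_lengths: Dict[str, int]
    cuts: Dict[str, np.ndarray]
    pattern: str = HINDIII_PATTERN
    cut_offset: int = HINDIII_CUT_OFFSET

    def fragments(self, chrom: str) -> np.ndarray:
        """Fragment boundaries for ``chrom``: array [0, c1, ..., ck, L]."""
        L = self.chrom_lengths[chrom]
        return np.concatenate(([0], self.cuts[chrom], [L]))

    def n_fragments(self, chrom: str) -> int:
        return len(self.cuts[chrom]) + 1

    def fragment_index(self, chrom: str, pos) -> np.ndarray:
        """0-based fragment ordinal containing each position (vectorized)."""
        return np.searchsorted(self.cuts[chrom], np.asarray(pos), side="right")

    def site_distance(self, chrom: str, pos) -> np.ndarray:
        """Distance from each position to the nearest cut site (vectorized).

        Chromosomes without any cut return +inf.
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        cuts = self.cuts[chrom]
        if len(cuts) == 0:
            return np.full(pos.shape, np.inf)
        idx = np.searchsorted(cuts, pos)
        left = np.where(idx > 0, np.abs(pos - cuts[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(
            idx < len(cuts), np.abs(cuts[np.minimum(idx, len(cuts) - 1)] - pos), np.inf
        )
        return np.minimum(left, right)

    def to_bed(self, path) -> None:
        """Write fragments as BED (chrom, start, end, fragment_id)."""
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                bounds = self.fragments(chrom)
                for k, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
                    fh.write(f"{chrom}\t{s}\t{e}\t{chrom}_frag{k}\n")


def digest_genome(
    genome: Mapping[str, str],
    pattern: str = HINDIII_PATTERN,
    cut_offset: int = HINDIII_CUT_OFFSET,
) -> FragmentMap:
    """Digest ``genome`` (chrom -> sequence) at every occurrence of ``pattern``.

    Cut coordinates are ``occurrence_start + cut_offset``.  Matching is exact
    over upper-cased sequence; IUPAC ambiguity codes never match.  A chromosome
    without any occurrence yields a single fragment covering it entirely.
    """
    if not genome:
        raise ValueError("empty genome: no chromosomes to digest")
    if not pattern:
        raise ValueError("empty recognition pattern")
    if not 0 <= cut_offset <= len(pattern):
        raise ValueError(f"cut_offset {cut_offset} outside pattern of length {len(pattern)}")
    pattern = pattern.upper()
    lengths: Dict[str, int] = {}
    cuts: Dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        lengths[chrom] = len(seq)
        occ = _find_occurrences(seq, pattern)
        c = occ + cut_offset
        # a cut at 0 or L would create an empty fragment; clip to interior
        cuts[chrom] = c[(c > 0) & (c < len(seq))]
    return FragmentMap(chrom_lengths=lengths, cuts=cuts, pattern=pattern, cut_offset=cut_offset)


def nearest_site_distance(chrom: str, pos: int, fmap: FragmentMap) -> float:
    """Minimum absolute distance from ``pos`` to any cut site on ``chrom``."""
    if chrom not in fmap.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < fmap.chrom_lengths[chrom]:
        raise ValueError(f"position {pos} outside chromosome {chrom}")
    return float(fmap.site_distance(chrom, pos)[0])


@dataclass
class BinGrid:
    """Fixed-resolution genome-wide binning with a linear bin index.

    Bin k of a chromosome covers [k*res, (k+1)*res), the last bin truncated at
    the chromosome end.  Linear indices concatenate chromosomes in insertion
    order; the mapping (chrom, ordinal) <-> linear index is a bijection.
    """

    chrom_lengths: Dict[str, int]
    resolution: int
    chroms: Tuple[str, ...] = field(init=False)
    n_bins_per_chrom: Dict[str, int] = field(init=False)
    offsets: Dict[str, int] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chroms = tuple(self.chrom_lengths)
        self.n_bins_per_chrom = {
            c: int(np.ceil(L / self.resolution)) for c, L in self.chrom_lengths.items()
        }
        self.offsets = {}
        total = 0
        for c in self.chroms:
            self.offsets[c] = total
            total += self.n_bins_per_chrom[c]
        self.n_bins = total
        # per-bin chromosome code and start coordinate, for vectorized lookups
        codes = np.empty(total, dtype=np.int32)
        starts = np.empty(total, dtype=np.int64)
        for ci, c in enumerate(self.chroms):
            o, n = self.offsets[c], self.n_bins_per_chrom[c]
            codes[o : o + n] = ci
            starts[o : o + n] = np.arange(n, dtype=np.int64) * self.resolution
        self.bin_chrom_code = codes
        self.bin_start = starts

    def bin_index(self, chrom, pos) -> np.ndarray:
        """Linear bin index for positions (vectorized over ``pos``)."""
        pos = np.asarray(pos, dtype=np.int64)
        return self.offsets[chrom] + pos // self.resolution

    def bin_location(self, idx: int) -> Tuple[str, int, int]:
        """(chrom, start, end) of linear bin ``idx``."""
        chrom = self.chroms[self.bin_chrom_code[idx]]
        start = int(self.bin_start[idx])
        end = min(start + self.resolution, self.chrom_lengths[chrom])
        return chrom, start, end

    def chrom_bins(self, chrom: str) -> np.ndarray:
        o = self.offsets[chrom]
        return np.arange(o, o + self.n_bins_per_chrom[chrom])


def annotate_bins(
    grid: BinGrid,
    fmap: FragmentMap,
    mapability: Mapping[str, Sequence[Tuple[int, int, float]]] | None = None,
):
    """Per-bin cut-site count and length-weighted mean mapability.

    ``mapability`` maps chromosome -> iterable of (start, end, score) with
    scores in [0, 1]; uncovered genome scores 0.  When no track is given every
    bin gets mapability 1.0, so the downstream >0.5 filter passes vacuously
    (synthetic genomes carry no alignability ambiguity).

    Returns ``(site_count, mean_mapability)`` as arrays over linear bins.
    """
    res = grid.resolution
    site_count = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom in grid.chroms:
        if chrom in fmap.cuts and len(fmap.cuts[chrom]):
            binned = grid.bin_index(chrom, fmap.cuts[chrom])
            np.add.at(site_count, binned, 1)
    if mapability is None:
        return site_count, np.ones(grid.n_bins)
    covered = np.zeros(grid.n_bins)
    for chrom, intervals in mapability.items():
        if chrom not in grid.chrom_lengths:
            raise ValueError(f"mapability track on unknown chromosome {chrom!r}")
        L = grid.chrom_lengths[chrom]
        for start, end, score in intervals:
            if start < 0 or end > L or start > end:
                raise ValueError(
                    f"mapability interval [{start},{end}) outside {chrom} of length {L}"
                )
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"mapability score {score} outside [0,1]")
            b0 = grid.offsets[chrom] + start // res
            b1 = grid.offsets[chrom] + (max(end - 1, start)) // res
            for b in range(b0, b1 + 1):
                bs = grid.bin_start[b]
                overlap = min(end, bs + res) - max(start, bs)
                if overlap > 0:
                    covered[b] += overlap * score
    bin_len = np.minimum(
        grid.bin_start + res,
        np.array([grid.chrom_lengths[grid.chroms[c]] for c in grid.bin_chrom_code]),
    ) - grid.bin_start
    return site_count, covered / bin_len
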