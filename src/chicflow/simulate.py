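"""Ground-truth simulator for capture Hi-C ditag libraries.

Every pipeline stage is testable closed-loop against this module: it emits a
ditag table together with the full generative truth — per-ditag artifact
labels, planted loop anchors, planted domains, per-bin bias factors and
capture flags.

The generative model mirrors the assumptions the analysis stages make:

* restriction sites planted at exponential gaps (mean 3 kb, the genome-wide
  HindIII average) on otherwise site-free random sequence;
* cis contact probability per locus pair follows a two-regime power law
  (exponent about -0.52 below 0.5 Mb, about -0.97 from 0.5 to 7 Mb),
  trans contacts uniform;
* per-bin multiplicative visibility bias b_i, log-normal, applied as
  b_i * b_j thinning — exactly the factorized model iterative correction
  assumes;
* capture enrichment: the configured fold F is the *measured* enrichment
  factor (on-target read-fraction ratio against an uncaptured library), so
  the on-target share of the library is f * F with f the pre-capture
  on-target probability (requires f * F <= 1);
* planted loops add Poisson extra mass at anchor bin pairs, scaled to
  fold x the local background expectation at that separation and capture
  class;
* planted domains multiply within-domain contact probability by a constant
  ratio;
* artifact classes (self-ligation, non-digestion, circularization, missing
  restriction site) are emitted with exactly the fragment geometry that
  triggers the corresponding filter rule, and PCR duplicates are literal
  copies of emitted ditags.

Runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ditags import DITAG_COLUMNS
from .restriction import BinGrid, FragmentMap, HINDIII_PATTERN

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "planted_fragment_map",
    "simulate_library",
    "simulate_decay_contacts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions of a simulated capture Hi-C experiment."""

    chrom_lengths: Dict[str, int] = dc_field(
        default_factory=lambda: {"chrS1": 20_000_000, "chrS2": 20_000_000}
    )
    site_spacing: float = 3_000.0          # mean restriction-site gap (bp)
    baits: List[Tuple[str, int, int]] = dc_field(default_factory=list)
    capture_fold: float = 130.0            # measured on-target enrichment factor
    alpha_short: float = -0.52             # decay exponent below the breakpoint
    alpha_long: float = -0.97              # decay exponent above the breakpoint
    breakpoint: float = 500_000.0
    d_min: float = 9_000.0                 # smallest simulated cis separation
    d_max: float = 7_000_000.0
    trans_fraction: float = 0.2
    bias_sigma: float = 0.3                # log-normal sigma of per-bin bias
    pair_dispersion_shape: float = 2.5     # Weibull shape of per-pair rate noise (0 = off)
    resolution: int = 9_000                # bin size for bias / loop placement
    loops: List[Tuple[str, int, str, int, float]] = dc_field(default_factory=list)
    domains: List[Tuple[str, int, int]] = dc_field(default_factory=list)
    domain_ratio: float = 3.0              # within/between contact ratio
    frac_self_ligation: float = 0.02
    frac_non_digested: float = 0.02
    frac_circularized: float = 0.01
    frac_no_site: float = 0.02
    frac_duplicate: float = 0.05
    library_size: int = 500_000
    end_jitter: int = 300                  # ends placed within this of a cut site
    seed: int = 0

    def artifact_fraction(self) -> float:
        return (
            self.frac_self_ligation + self.frac_non_digested
            + self.frac_circularized + self.frac_no_site + self.frac_duplicate
        )

    def validate(self) -> None:
        for name in ("frac_self_ligation", "frac_non_digested", "frac_circularized",
                     "frac_no_site", "frac_duplicate", "trans_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.artifact_fraction() >= 1.0:
            raise ValueError("artifact fractions must sum to less than 1")
        if self.capture_fold < 1.0:
            raise ValueError("capture_fold below 1 is not an enrichment")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    labels: np.ndarray                 # per-ditag artifact label (covers all rows)
    bias: np.ndarray                   # per-bin multiplicative bias factors
    grid: BinGrid
    loops: List[Tuple[int, int, float]]       # planted anchors as (bin_i, bin_j, fold)
    domains: List[Tuple[str, int, int]]
    on_target: np.ndarray              # per-ditag capture flag
    loop_id: np.ndarray                # planted loop index per ditag, -1 otherwise


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _plant_cut_positions(L: int, spacing: float, rng) -> np.ndarray:
    """Site start positions with exponential gaps, interior to [1, L - 7]."""
    n_est = int(L / spacing * 1.5) + 10
    gaps = rng.exponential(spacing, size=n_est)
    gaps = np.maximum(gaps, 2 * len(HINDIII_PATTERN))  # no overlapping sites
    pos = np.cumsum(gaps).astype(np.int64)
    return pos[(pos >= 1) & (pos <= L - len(HINDIII_PATTERN) - 1)]


def planted_fragment_map(cfg: SimulationConfig, rng=None) -> Tuple[FragmentMap, Dict[str, np.ndarray]]:
    """FragmentMap built directly from planted cut lists (no sequence).

    The cut coordinate equals site start + 1, matching HindIII's A^AGCTT
    offset, so a digest of the corresponding simulated sequence recovers it.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    cuts = {}
    sites = {}
    for chrom, L in cfg.chrom_lengths.items():
        starts = _plant_cut_positions(L, cfg.site_spacing, rng)
        sites[chrom] = starts
        cuts[chrom] = starts + 1
    fmap = FragmentMap(chrom_lengths=dict(cfg.chrom_lengths), cuts=cuts)
    return fmap, sites


def simulate_genome(
    cfg: SimulationConfig, rng=None
) -> Tuple[Dict[str, str], Dict[str, np.ndarray]]:
    """Random genome with restriction sites planted at exponential gaps.

    Returns (genome, planted site starts).  The pattern occurs nowhere except
    the planted positions, so an in-silico digest recovers exactly the
    planted list.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    pattern = np.frombuffer(HINDIII_PATTERN.encode(), dtype="S1")
    genome: Dict[str, str] = {}
    site_truth: Dict[str, np.ndarray] = {}
    for chrom, L in cfg.chrom_lengths.items():
        starts = _plant_cut_positions(L, cfg.site_spacing, rng)
        seq = _BASES[rng.integers(0, 4, size=L)]
        planted = np.zeros(L, dtype=bool)
        for p in starts:
            seq[p : p + 6] = pattern
            planted[p : p + 6] = True
        # scrub accidental occurrences outside planted spans
        s = seq.tobytes()
        while True:
            hits = []
            start = s.find(b"AAGCTT")
            while start != -1:
                hits.append(start)
                start = s.find(b"AAGCTT", start + 1)
            accidental = [h for h in hits if h not in set(starts.tolist())]
            if not accidental:
                break
            for h in accidental:
                # mutate one base of the occurrence lying outside planted spans
                for off in range(6):
                    if not planted[h + off]:
                        want = b"AAGCTT"[off : off + 1]
                        repl = b"C" if want != b"C" else b"G"
                        seq[h + off] = repl
                        break
            s = seq.tobytes()
        genome[chrom] = s.decode()
        site_truth[chrom] = starts
    return genome, site_truth


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def _decay(d: np.ndarray, alpha_short: float, alpha_long: float, bp: float) -> np.ndarray:
    """Two-regime power law, continuous at the breakpoint."""
    d = np.asarray(d, dtype=float)
    c = bp ** (alpha_short - alpha_long)  # matches the regimes at d = bp
    return np.where(d < bp, d**alpha_short, c * d**alpha_long)


def _sample_separations(
    n: int, L: float, rng, alpha_short: float, alpha_long: float,
    bp: float, d_min: float, d_max: float, pair_factor: bool = True,
) -> np.ndarray:
    """Separations with density prop. to decay(d) * (L - d) on [d_min, d_max].

    The (L - d) factor makes the *per locus pair* contact probability follow
    the power law, which is what the expected-contacts template estimates;
    ``pair_factor=False`` drops it, giving the separation law conditional on
    one fixed end (used for bait-anchored sampling).
    """
    hi = min(d_max, L - 1)
    if hi <= d_min:
        raise ValueError("chromosome too short for the configured separation range")
    grid = np.exp(np.linspace(np.log(d_min), np.log(hi), 4096))
    dens = _decay(grid, alpha_short, alpha_long, bp)
    if pair_factor:
        dens = dens * (L - grid)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))))
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def simulate_decay_contacts(
    n: int,
    length: int = 20_000_000,
    alpha: float = -0.97,
    d_min: float = 500_000.0,
    d_max: float = 7_000_000.0,
    chrom: str = "chrS1",
    seed: int = 0,
) -> pd.DataFrame:
    """Pure single-regime power-law cis contacts, uniform in position.

    The per-pair contact probability is proportional to d**alpha restricted
    to [d_min, d_max]; used to check that the distance-template fit recovers
    a known exponent.
    """
    rng = np.random.default_rng(seed)
    d = _sample_separations(n, float(length), rng, alpha, alpha, d_max, d_min, d_max)
    u = rng.random(n) * (length - d)
    p1 = u.astype(np.int64)
    p2 = (u + d).astype(np.int64)

    def const(label):
        return pd.Categorical.from_codes(np.zeros(n, dtype=np.int8), [label])

    return pd.DataFrame(
        {
            "read_id": np.arange(n),
            "chrom1": const(chrom), "pos1": p1, "strand1": const("+"),
            "mapq1": np.full(n, 60, dtype=np.int16),
            "chrom2": const(chrom), "pos2": p2, "strand2": const("-"),
            "mapq2": np.full(n, 60, dtype=np.int16),
        }
    )


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def _snap_to_sites(fmap: FragmentMap, chrom: str, pos: np.ndarray, jitter: int, rng):
    """Move positions next to their nearest cut site (within +-jitter)."""
    cuts = fmap.cuts[chrom]
    if len(cuts) == 0:
        return np.clip(pos, 0, fmap.chrom_lengths[chrom] - 1)
    idx = np.searchsorted(cuts, pos)
    left = cuts[np.clip(idx - 1, 0, len(cuts) - 1)]
    right = cuts[np.clip(idx, 0, len(cuts) - 1)]
    nearest = np.where(np.abs(pos - left) <= np.abs(right - pos), left, right)
    off = rng.integers(-jitter, jitter + 1, size=len(pos))
    return np.clip(nearest + off, 0, fmap.chrom_lengths[chrom] - 1)


def _pair_noise(cfg, grid, bin1: np.ndarray, bin2: np.ndarray) -> np.ndarray:
    """Quenched per-bin-pair rate multiplier: Weibull-distributed, mean 1.

    Contact frequencies between fixed locus pairs vary far beyond Poisson in
    real Hi-C (local chromatin structure, residual biases), and the observed
    strength distribution is Weibull-like — the very reason a Weibull null is
    fitted downstream.  Multipliers are therefore drawn from a mean-1 Weibull
    with shape ``pair_dispersion_shape`` (clipped at the 1-1e-4 quantile) and
    are deterministic in (seed, pair) via splitmix64, so every candidate for
    the same pair sees the same multiplier.
    """
    shape = cfg.pair_dispersion_shape
    if shape <= 0:
        return np.ones(len(bin1))
    from scipy.special import gamma as gamma_fn

    key = bin1.astype(np.uint64) * np.uint64(grid.n_bins) + bin2.astype(np.uint64)
    z = key + np.uint64((cfg.seed * 0x9E3779B97F4A7C15 + 0x632BE59BD9B4E019) % 2**64)
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    u = (z >> np.uint64(11)).astype(np.float64) * 2.0**-53
    u = np.clip(u, 1e-12, 1.0 - 1e-4)  # upper clip bounds the multiplier
    mean = gamma_fn(1.0 + 1.0 / shape)
    return (-np.log1p(-u)) ** (1.0 / shape) / mean


def _pair_noise_max(cfg) -> float:
    shape = cfg.pair_dispersion_shape
    if shape <= 0:
        return 1.0
    from scipy.special import gamma as gamma_fn

    return float((-np.log(1e-4)) ** (1.0 / shape) / gamma_fn(1.0 + 1.0 / shape))


def _domain_code(cfg: SimulationConfig, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Planted-domain index per position, -1 outside any domain."""
    code = np.full(len(pos), -1, dtype=np.int64)
    for di, (dc, ds, de) in enumerate(cfg.domains):
        inside = (chrom == dc) & (pos >= ds) & (pos < de)
        code[inside] = di
    return code


def _cis_candidates(cfg, fmap, grid, bias, n: int, rng) -> pd.DataFrame:
    """Raw cis candidates after bias/domain thinning, before capture split."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    frames = []
    got = 0
    bias_max2 = bias.max() ** 2 * max(cfg.domain_ratio, 1.0) * _pair_noise_max(cfg)
    while got < n:
        m = int((n - got) * 1.6 / max(0.05, (bias.mean() ** 2) / bias_max2)) + 1000
        m = min(m, 4_000_000)
        ci = rng.choice(len(chroms), size=m, p=probs)
        frames_chunk = []
        for k, chrom in enumerate(chroms):
            sel = ci == k
            mm = int(sel.sum())
            if mm == 0:
                continue
            L = float(cfg.chrom_lengths[chrom])
            d = _sample_separations(
                mm, L, rng, cfg.alpha_short, cfg.alpha_long,
                cfg.breakpoint, cfg.d_min, cfg.d_max,
            )
            u = rng.random(mm) * (L - d)
            p1 = _snap_to_sites(fmap, chrom, u.astype(np.int64), cfg.end_jitter, rng)
            p2 = _snap_to_sites(fmap, chrom, (u + d).astype(np.int64), cfg.end_jitter, rng)
            lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
            f1 = fmap.fragment_index(chrom, lo)
            f2 = fmap.fragment_index(chrom, hi)
            ok = (f2 - f1) >= 2  # geometry that can never trigger an artifact rule
            lo, hi = lo[ok], hi[ok]
            b1 = bias[grid.bin_index(chrom, lo)]
            b2 = bias[grid.bin_index(chrom, hi)]
            w = b1 * b2
            dcode1 = _domain_code(cfg, np.repeat(chrom, len(lo)), lo)
            dcode2 = _domain_code(cfg, np.repeat(chrom, len(hi)), hi)
            same_dom = (dcode1 >= 0) & (dcode1 == dcode2)
            w = w * np.where(same_dom, cfg.domain_ratio, 1.0)
            w = w * _pair_noise(cfg, grid, grid.bin_index(chrom, lo),
                                grid.bin_index(chrom, hi))
            accept = rng.random(len(lo)) < w / bias_max2
            lo, hi = lo[accept], hi[accept]
            frames_chunk.append(pd.DataFrame({"chrom1": chrom, "pos1": lo,
                                              "chrom2": chrom, "pos2": hi}))
        if frames_chunk:
            chunk = pd.concat(frames_chunk, ignore_index=True)
            frames.append(chunk)
            got += len(chunk)
    return pd.concat(frames, ignore_index=True)


def _trans_candidates(cfg, fmap, grid, bias, n: int, rng) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    if len(chroms) < 2:
        return pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    got = 0
    bias_max2 = bias.max() ** 2 * _pair_noise_max(cfg)
    while got < n:
        m = int((n - got) * 1.6 * bias_max2 / (bias.mean() ** 2)) + 1000
        c1 = rng.choice(len(chroms), size=m, p=probs)
        c2 = rng.choice(len(chroms), size=m, p=probs)
        diff = c1 != c2
        c1, c2 = c1[diff], c2[diff]
        rows = {k: [] for k in ("chrom1", "pos1", "chrom2", "pos2")}
        p1 = np.empty(len(c1), dtype=np.int64)
        p2 = np.empty(len(c1), dtype=np.int64)
        for k, chrom in enumerate(chroms):
            for arr, cc in ((p1, c1), (p2, c2)):
                sel = cc == k
                if sel.any():
                    raw = (rng.random(int(sel.sum())) * cfg.chrom_lengths[chrom]).astype(np.int64)
                    arr[sel] = _snap_to_sites(fmap, chrom, raw, cfg.end_jitter, rng)
        name1 = np.array(chroms, dtype=object)[c1]
        name2 = np.array(chroms, dtype=object)[c2]
        b1 = np.empty(len(c1))
        b2 = np.empty(len(c1))
        for k, chrom in enumerate(chroms):
            s1 = c1 == k
            s2 = c2 == k
            if s1.any():
                b1[s1] = bias[grid.bin_index(chrom, p1[s1])]
            if s2.any():
                b2[s2] = bias[grid.bin_index(chrom, p2[s2])]
        g1 = np.empty(len(c1), dtype=np.int64)
        g2 = np.empty(len(c1), dtype=np.int64)
        for k, chrom in enumerate(chroms):
            s1m = c1 == k
            s2m = c2 == k
            if s1m.any():
                g1[s1m] = grid.bin_index(chrom, p1[s1m])
            if s2m.any():
                g2[s2m] = grid.bin_index(chrom, p2[s2m])
        w = b1 * b2 * _pair_noise(cfg, grid, np.minimum(g1, g2), np.maximum(g1, g2))
        accept = rng.random(len(c1)) < w / bias_max2
        chunk = pd.DataFrame(
            {"chrom1": name1[accept], "pos1": p1[accept],
             "chrom2": name2[accept], "pos2": p2[accept]}
        )
        out.append(chunk)
        got += len(chunk)
    return pd.concat(out, ignore_index=True)


def _cis_candidates_baited(cfg, fmap, grid, bias, n: int, rng) -> pd.DataFrame:
    """Cis candidates conditioned on one end inside a bait interval.

    With one end fixed, the separation law loses the (L - d) pair factor;
    bias/domain thinning applies as in the unconditioned generator.
    """
    baits = [b for b in cfg.baits if b[0] in cfg.chrom_lengths]
    if not baits:
        return pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    bl = np.array([e - s for _, s, e in baits], dtype=float)
    bprob = bl / bl.sum()
    frames = []
    got = 0
    bias_max2 = bias.max() ** 2 * max(cfg.domain_ratio, 1.0) * _pair_noise_max(cfg)
    while got < n:
        m = int((n - got) * 1.6 / max(0.05, (bias.mean() ** 2) / bias_max2)) + 1000
        pick = rng.choice(len(baits), size=m, p=bprob)
        for bi, (chrom, bs, be) in enumerate(baits):
            sel = pick == bi
            mm = int(sel.sum())
            if mm == 0:
                continue
            L = float(cfg.chrom_lengths[chrom])
            x1 = bs + (rng.random(mm) * (be - bs)).astype(np.int64)
            d = _sample_separations(
                mm, L, rng, cfg.alpha_short, cfg.alpha_long,
                cfg.breakpoint, cfg.d_min, cfg.d_max, pair_factor=False,
            )
            sign = rng.integers(0, 2, mm) * 2 - 1
            x2 = x1 + (sign * d).astype(np.int64)
            ok = (x2 >= 0) & (x2 < L)
            x1, x2 = x1[ok], x2[ok]
            p1 = _snap_to_sites(fmap, chrom, x1, cfg.end_jitter, rng)
            p2 = _snap_to_sites(fmap, chrom, x2, cfg.end_jitter, rng)
            lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
            f1 = fmap.fragment_index(chrom, lo)
            f2 = fmap.fragment_index(chrom, hi)
            good = (f2 - f1) >= 2
            lo, hi = lo[good], hi[good]
            w = bias[grid.bin_index(chrom, lo)] * bias[grid.bin_index(chrom, hi)]
            dc1 = _domain_code(cfg, np.repeat(chrom, len(lo)), lo)
            dc2 = _domain_code(cfg, np.repeat(chrom, len(hi)), hi)
            w = w * np.where((dc1 >= 0) & (dc1 == dc2), cfg.domain_ratio, 1.0)
            w = w * _pair_noise(cfg, grid, grid.bin_index(chrom, lo),
                                grid.bin_index(chrom, hi))
            accept = rng.random(len(lo)) < w / bias_max2
            frames.append(pd.DataFrame({"chrom1": chrom, "pos1": lo[accept],
                                        "chrom2": chrom, "pos2": hi[accept]}))
        got = sum(len(f) for f in frames)
    return pd.concat(frames, ignore_index=True)


def _trans_candidates_baited(cfg, fmap, grid, bias, n: int, rng) -> pd.DataFrame:
    """Trans candidates with one end inside a bait interval."""
    chroms = list(cfg.chrom_lengths)
    baits = [b for b in cfg.baits if b[0] in cfg.chrom_lengths]
    if not baits or len(chroms) < 2:
        return pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    bl = np.array([e - s for _, s, e in baits], dtype=float)
    bprob = bl / bl.sum()
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    frames = []
    got = 0
    bias_max2 = bias.max() ** 2 * _pair_noise_max(cfg)
    while got < n:
        m = int((n - got) * 1.6 / max(0.05, (bias.mean() ** 2) / bias_max2)) + 1000
        pick = rng.choice(len(baits), size=m, p=bprob)
        for bi, (chrom, bs, be) in enumerate(baits):
            sel = pick == bi
            mm = int(sel.sum())
            if mm == 0:
                continue
            others = [k for k, c in enumerate(chroms) if c != chrom]
            oprob = lengths[others] / lengths[others].sum()
            x1 = bs + (rng.random(mm) * (be - bs)).astype(np.int64)
            p1 = _snap_to_sites(fmap, chrom, x1, cfg.end_jitter, rng)
            oc = rng.choice(others, size=mm, p=oprob)
            p2 = np.empty(mm, dtype=np.int64)
            name2 = np.array(chroms, dtype=object)[oc]
            for k in others:
                s2 = oc == k
                if s2.any():
                    raw = (rng.random(int(s2.sum())) * cfg.chrom_lengths[chroms[k]]).astype(np.int64)
                    p2[s2] = _snap_to_sites(fmap, chroms[k], raw, cfg.end_jitter, rng)
            g1 = grid.bin_index(chrom, p1)
            b1 = bias[g1]
            b2 = np.empty(mm)
            g2 = np.empty(mm, dtype=np.int64)
            for k in others:
                s2 = oc == k
                if s2.any():
                    g2[s2] = grid.bin_index(chroms[k], p2[s2])
                    b2[s2] = bias[g2[s2]]
            w = b1 * b2 * _pair_noise(cfg, grid, np.minimum(g1, g2), np.maximum(g1, g2))
            accept = rng.random(mm) < w / bias_max2
            frames.append(pd.DataFrame({"chrom1": chrom, "pos1": p1[accept],
                                        "chrom2": name2[accept], "pos2": p2[accept]}))
        got = sum(len(f) for f in frames)
    return pd.concat(frames, ignore_index=True)


def _touches_bait(cfg, grid, enriched: np.ndarray, df: pd.DataFrame) -> np.ndarray:
    """Either end inside a bait *interval*: capture pulls down sequence that
    overlaps a bait, irrespective of the analysis binning."""
    hit = np.zeros(len(df), dtype=bool)
    by_chrom: Dict[str, list] = {}
    for chrom, bs, be in cfg.baits:
        by_chrom.setdefault(chrom, []).append((bs, be))
    for ccol, pcol in (("chrom1", "pos1"), ("chrom2", "pos2")):
        for chrom, ivs in by_chrom.items():
            m = (df[ccol] == chrom).to_numpy()
            if m.any():
                pos = df.loc[m, pcol].to_numpy()
                inside = np.zeros(len(pos), dtype=bool)
                for bs, be in ivs:
                    inside |= (pos >= bs) & (pos < be)
                hit[m] |= inside
    return hit


def _capture_split(cfg, grid, enriched, candidates: pd.DataFrame, n: int, rng,
                   baited_generator=None):
    """Compose n ditags with on-target share f * capture_fold.

    The measured enrichment factor F is the on-target fraction ratio against
    the uncaptured pool, whose on-target probability f the pool estimates
    directly; the captured library's on-target share is then exactly f * F.
    On-target ditags beyond what the unconditioned pool holds come from a
    bait-anchored generator (capture makes rare candidates common).
    """
    on = _touches_bait(cfg, grid, enriched, candidates)
    f = float(on.mean())
    if cfg.capture_fold > 1.0 and enriched.any():
        q = f * cfg.capture_fold
        if q > 1.0:
            raise ValueError(
                f"capture fold {cfg.capture_fold} infeasible: baits cover too much "
                f"of the genome (base on-target probability {f:.3g})"
            )
    else:
        q = f
    n_on = int(rng.binomial(n, q)) if 0.0 < q < 1.0 else (n if q >= 1.0 else 0)
    pool_on = candidates[on]
    if n_on > len(pool_on):
        if baited_generator is None:
            raise ValueError("candidate pool exhausted; increase oversampling")
        extra = baited_generator(int((n_on - len(pool_on)) * 1.3) + 200)
        extra = extra[_touches_bait(cfg, grid, enriched, extra)]
        pool_on = pd.concat([pool_on, extra], ignore_index=True)
        if n_on > len(pool_on):
            raise ValueError("bait-anchored candidate pool exhausted")
    pool_off = candidates[~on]
    if (n - n_on) > len(pool_off):
        raise ValueError("candidate pool exhausted; increase oversampling")
    take_on = pool_on.iloc[rng.choice(len(pool_on), n_on, replace=False)]
    take_off = pool_off.iloc[rng.choice(len(pool_off), n - n_on, replace=False)]
    out = pd.concat([take_on, take_off], ignore_index=True)
    flags = np.concatenate([np.ones(n_on, bool), np.zeros(n - n_on, bool)])
    return out, flags


def _loop_extra(cfg, fmap, grid, enriched, cis: pd.DataFrame, rng):
    """Poisson extra ditags at planted loop anchors, fold x local background."""
    if not cfg.loops:
        return (pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"]),
                np.array([], dtype=np.int64), [])
    res = cfg.resolution
    # bin the generated cis background once
    bi = np.empty(len(cis), dtype=np.int64)
    bj = np.empty(len(cis), dtype=np.int64)
    for chrom in grid.chroms:
        m = (cis["chrom1"] == chrom).to_numpy()
        if m.any():
            bi[m] = grid.bin_index(chrom, cis.loc[m, "pos1"].to_numpy())
        m2 = (cis["chrom2"] == chrom).to_numpy()
        if m2.any():
            bj[m2] = grid.bin_index(chrom, cis.loc[m2, "pos2"].to_numpy())
    lo = np.minimum(bi, bj)
    hi = np.maximum(bi, bj)
    pair_key = lo * grid.n_bins + hi
    key_counts = pd.Series(pair_key).value_counts()

    anchors: List[Tuple[int, int, float]] = []
    rows = []
    loop_ids = []
    for li, (c1, p1, c2, p2, fold) in enumerate(cfg.loops):
        a = int(grid.bin_index(c1, p1))
        b = int(grid.bin_index(c2, p2))
        if a > b:  # keep anchor 1 the lower linear bin
            a, b = b, a
            c1, p1, c2, p2 = c2, p2, c1, p1
        anchors.append((a, b, fold))
        k = abs(b - a)
        # local background: same-class pairs at similar separation on c1
        bins_c = grid.chrom_bins(c1)
        band = [kk for kk in range(max(1, int(k * 0.8)), int(k * 1.25) + 1)]
        tot, npairs = 0.0, 0
        cls = enriched[a] or enriched[b]
        for kk in band:
            ii = bins_c[: len(bins_c) - kk]
            jj = ii + kk
            same = (enriched[ii] | enriched[jj]) == cls
            keys = ii[same] * grid.n_bins + jj[same]
            tot += key_counts.reindex(keys).fillna(0).sum()
            npairs += int(same.sum())
        mu = tot / max(npairs, 1)
        # scale by the interactor bin's relative cis coverage so the planted
        # mass carries the same per-bin visibility as its background; the
        # anchor-side (bait) scale is shared with the band and cancels
        band_cols = np.unique(np.concatenate(
            [bins_c[: len(bins_c) - kk] + kk for kk in band]
        ))
        band_cols = band_cols[~enriched[band_cols]]  # compare like with like
        col_counts = np.bincount(np.concatenate([lo, hi]), minlength=grid.n_bins)
        band_cov = col_counts[band_cols]
        cov_factor = 1.0
        if band_cov.mean() > 0 and col_counts[b] > 0:
            cov_factor = col_counts[b] / band_cov.mean()
        extra = int(rng.poisson(max(fold - 1.0, 0.0) * mu * cov_factor))
        if extra == 0:
            continue
        s1 = int(grid.bin_start[a])
        s2 = int(grid.bin_start[b])
        q1 = _snap_to_sites(fmap, c1, s1 + rng.integers(0, res, extra), cfg.end_jitter, rng)
        q2 = _snap_to_sites(fmap, c2, s2 + rng.integers(0, res, extra), cfg.end_jitter, rng)
        # keep ends inside the anchor bins so the planted signal stays put
        q1 = np.clip(q1, s1, s1 + res - 1)
        q2 = np.clip(q2, s2, s2 + res - 1)
        rows.append(pd.DataFrame({"chrom1": c1, "pos1": np.minimum(q1, q2) if c1 == c2 else q1,
                                  "chrom2": c2, "pos2": np.maximum(q1, q2) if c1 == c2 else q2}))
        loop_ids.extend([li] * extra)
    if rows:
        extra_df = pd.concat(rows, ignore_index=True)
    else:
        extra_df = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    return extra_df, np.asarray(loop_ids, dtype=np.int64), anchors


def _artifact_ditags(cfg, fmap, rng) -> Tuple[pd.DataFrame, np.ndarray]:
    """Background ditags with geometry matching each filter rule exactly."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    specs = [
        ("self_ligation", int(round(cfg.frac_self_ligation * cfg.library_size))),
        ("non_digested", int(round(cfg.frac_non_digested * cfg.library_size))),
        ("circularized", int(round(cfg.frac_circularized * cfg.library_size))),
        ("no_site", int(round(cfg.frac_no_site * cfg.library_size))),
    ]
    rows = []
    labels = []
    for label, count in specs:
        made = 0
        guard = 0
        while made < count and guard < count * 50 + 100:
            guard += 1
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            cuts = fmap.cuts[chrom]
            if len(cuts) < 3:
                continue
            if label in ("self_ligation", "non_digested"):
                k = int(rng.integers(0, len(cuts) - 1))
                a, b = int(cuts[k]), int(cuts[k + 1])
                if b - a < 120:
                    continue
                off = min(300, (b - a) // 2 - 10)
                p1 = a + int(rng.integers(10, off + 1))
                p2 = b - int(rng.integers(10, off + 1))
                if p1 >= p2:
                    continue
                s1, s2 = ("-", "+") if label == "self_ligation" else ("+", "-")
            elif label == "circularized":
                k = int(rng.integers(1, len(cuts) - 1))
                a0, a1, a2 = int(cuts[k - 1]), int(cuts[k]), int(cuts[k + 1])
                if a1 - a0 < 120 or a2 - a1 < 120:
                    continue
                p1 = a0 + int(rng.integers(10, min(300, a1 - a0 - 10) + 1))
                p2 = a2 - int(rng.integers(10, min(300, a2 - a1 - 10) + 1))
                s1, s2 = "-", "+"  # outward on adjacent fragments
            else:  # no_site: one end marooned mid-fragment, far from any cut
                k = int(rng.integers(0, len(cuts) - 1))
                a, b = int(cuts[k]), int(cuts[k + 1])
                if b - a < 2_000:
                    continue
                p1 = (a + b) // 2
                far = float(fmap.site_distance(chrom, [p1])[0])
                if far <= 850:
                    continue
                j = int(rng.integers(0, len(cuts)))
                p2 = int(np.clip(cuts[j] + rng.integers(-200, 201),
                                 0, cfg.chrom_lengths[chrom] - 1))
                if abs(p2 - p1) < 20_000:
                    continue
                if p1 > p2:
                    p1, p2 = p2, p1
                s1, s2 = "+", "-"
            rows.append((chrom, p1, s1, chrom, p2, s2))
            labels.append(label)
            made += 1
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "strand1",
                                     "chrom2", "pos2", "strand2"])
    return df, np.asarray(labels, dtype=object)


def simulate_library(
    cfg: SimulationConfig,
    fmap: FragmentMap | None = None,
    seed: int | None = None,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Emit a ditag table plus ground truth under the configured conditions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if fmap is None:
        fmap, _ = planted_fragment_map(cfg, rng)
    grid = BinGrid(dict(cfg.chrom_lengths), cfg.resolution)
    bias = rng.lognormal(0.0, cfg.bias_sigma, grid.n_bins) if cfg.bias_sigma > 0 else np.ones(grid.n_bins)
    from .matrix import mark_enriched_bins

    enriched = mark_enriched_bins(grid, cfg.baits)

    n_total = cfg.library_size
    n_art = {
        "self_ligation": int(round(cfg.frac_self_ligation * n_total)),
        "non_digested": int(round(cfg.frac_non_digested * n_total)),
        "circularized": int(round(cfg.frac_circularized * n_total)),
        "no_site": int(round(cfg.frac_no_site * n_total)),
    }
    n_dup = int(round(cfg.frac_duplicate * n_total))
    n_valid = n_total - sum(n_art.values()) - n_dup
    n_trans = int(round(cfg.trans_fraction * n_valid)) if len(cfg.chrom_lengths) > 1 else 0
    n_cis = n_valid - n_trans

    cis_pool = _cis_candidates(cfg, fmap, grid, bias, int(n_cis * 1.3) + 500, rng)
    cis, cis_on = _capture_split(
        cfg, grid, enriched, cis_pool, n_cis, rng,
        baited_generator=lambda k: _cis_candidates_baited(cfg, fmap, grid, bias, k, rng),
    )
    if n_trans > 0:
        trans_pool = _trans_candidates(cfg, fmap, grid, bias, int(n_trans * 1.3) + 500, rng)
        trans, trans_on = _capture_split(
            cfg, grid, enriched, trans_pool, n_trans, rng,
            baited_generator=lambda k: _trans_candidates_baited(cfg, fmap, grid, bias, k, rng),
        )
    else:
        trans = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
        trans_on = np.array([], dtype=bool)

    extra, extra_loop_ids, anchors = _loop_extra(cfg, fmap, grid, enriched, cis, rng)

    background = pd.concat([cis, trans, extra], ignore_index=True)
    bg_strand1 = np.array(["+", "-"])[rng.integers(0, 2, len(background))]
    bg_strand2 = np.array(["+", "-"])[rng.integers(0, 2, len(background))]
    background["strand1"] = bg_strand1
    background["strand2"] = bg_strand2
    bg_labels = np.array(["valid"] * len(background), dtype=object)
    bg_loop = np.full(len(background), -1, dtype=np.int64)
    if len(extra_loop_ids):
        bg_loop[len(cis) + len(trans):] = extra_loop_ids
    bg_on = np.concatenate([cis_on, trans_on, np.ones(len(extra), dtype=bool)])

    art, art_labels = _artifact_ditags(cfg, fmap, rng)

    frames = [background[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]]]
    labels = [bg_labels]
    loop_ids = [bg_loop]
    on_flags = [bg_on]
    if len(art):
        frames.append(art)
        labels.append(art_labels)
        loop_ids.append(np.full(len(art), -1, dtype=np.int64))
        on_flags.append(np.zeros(len(art), dtype=bool))
    table = pd.concat(frames, ignore_index=True)
    labels = np.concatenate(labels)
    loop_ids = np.concatenate(loop_ids)
    on_flags = np.concatenate(on_flags)

    # PCR duplicates: literal copies of emitted ditags
    if n_dup > 0 and len(table):
        src = rng.choice(len(table), size=n_dup, replace=True)
        dup = table.iloc[src].reset_index(drop=True)
        table = pd.concat([table, dup], ignore_index=True)
        labels = np.concatenate([labels, np.full(n_dup, "duplicate", dtype=object)])
        loop_ids = np.concatenate([loop_ids, np.full(n_dup, -1, dtype=np.int64)])
        on_flags = np.concatenate([on_flags, on_flags[src]])

    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    labels = labels[order]
    loop_ids = loop_ids[order]
    on_flags = on_flags[order]

    table.insert(0, "read_id", [f"sim{i:08d}" for i in range(len(table))])
    table["mapq1"] = 60
    table["mapq2"] = 60
    table = table[DITAG_COLUMNS]
    truth = GroundTruth(
        labels=labels, bias=bias, grid=grid, loops=anchors,
        domains=list(cfg.domains), on_target=on_flags, loop_id=loop_ids,
    )
    return table, truth
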