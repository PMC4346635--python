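"""Capture-aware iterative bias correction and distance normalization.

Bias correction adapts the iterative-correction idea to the target-enriched
setting: the visibility weight of bin i is estimated from its *trans*
contacts only, because capture enrichment inflates cis coverage around baits
in a distance-structured way while trans contacts sample visibility close to
uniformly.  Per bin we track

* ``w_i`` — total trans contact count of bin i,
* ``N_i`` — number of populated (nonzero) trans entries in row i,

and globally ``W = sum w_i``, ``A = sum N_i``.  The normalized weight

    w_hat_i = (w_i / N_i) * (A / W)

is the per-populated-entry rate of bin i relative to the global rate; the
recursion divides M_ij by w_hat_i * w_hat_j and recomputes weights until all
w_hat_i converge to unity.  Bins whose initial weight falls more than three
standard deviations below the mean weight are discarded before iterating.

Distance normalization divides every cis entry by the expected contact
frequency at its separation, read off a smoothed genome-wide template whose
log-log slope exhibits two power-law regimes (short-range exponent about
-0.52 over 9 kb - 0.5 Mb, long-range about -0.97 over 0.5 - 7 Mb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .matrix import ContactMatrix

__all__ = [
    "NormalizationState",
    "DistanceTemplate",
    "compute_weights",
    "iterative_bias_correct",
    "estimate_distance_template",
    "distance_normalize",
    "SHORT_RANGE", "LONG_RANGE",
]

#: power-law regime bounds (bases): 9 kb < d < 0.5 Mb and 0.5 Mb <= d <= 7 Mb
SHORT_RANGE = (9_000, 500_000)
LONG_RANGE = (500_000, 7_000_000)


@dataclass
class NormalizationState:
    """Per-bin weights and global aggregates of the bias-correction recursion."""

    w: np.ndarray            # per-bin trans contact count
    n_populated: np.ndarray  # per-bin populated trans entries
    W: float                 # sum of w over retained bins
    A: float                 # sum of n_populated over retained bins
    w_hat: np.ndarray        # normalized weights (1.0 where undefined)
    retained: np.ndarray     # bins participating in the recursion
    iteration: int = 0
    tol: float = 1e-3
    converged: bool = False

    def max_deviation(self) -> float:
        if not self.retained.any():
            return 0.0
        return float(np.max(np.abs(self.w_hat[self.retained] - 1.0)))


def _trans_weights(cm: ContactMatrix, retained: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(w_i, N_i) from trans entries among retained bins, symmetric counting.

    With a capture design (any enriched bins), only E-E / E-N entries carry
    analyzable signal and enter the weights: the N-N trans mass is so sparse
    that populated-entry counts track contact counts one-to-one, which would
    drive every per-populated-entry rate to unity and hide the very bias the
    recursion must estimate.
    """
    r, c, v = cm.coo(values=True)
    keep = retained[r] & retained[c] & cm.is_trans(r, c)
    if cm.enriched is not None and cm.enriched.any():
        keep &= cm.enriched[r] | cm.enriched[c]
    w = np.zeros(cm.n_bins)
    npop = np.zeros(cm.n_bins)
    r, c, v = r[keep], c[keep], v[keep]
    np.add.at(w, r, v)
    np.add.at(w, c, v)
    nz = v > 0
    np.add.at(npop, r[nz], 1)
    np.add.at(npop, c[nz], 1)
    return w, npop


def compute_weights(cm: ContactMatrix) -> NormalizationState:
    """Initial NormalizationState from the trans entries of a filtered matrix."""
    retained = cm.valid.copy()
    w, npop = _trans_weights(cm, retained)
    if not (w[retained] > 0).any():
        warnings.warn(
            "matrix has no trans contacts among valid bins; "
            "bias weights are degenerate (all zero)",
            stacklevel=2,
        )
    W = float(w[retained].sum())
    A = float(npop[retained].sum())
    w_hat = np.ones(cm.n_bins)
    ok = retained & (npop > 0) & (W > 0)
    if A > 0 and W > 0:
        w_hat[ok] = (w[ok] / npop[ok]) * (A / W)
    return NormalizationState(
        w=w, n_populated=npop, W=W, A=A, w_hat=w_hat, retained=retained
    )


def iterative_bias_correct(
    cm: ContactMatrix,
    tol: float = 1e-3,
    max_iter: int = 100,
    omega: float = 0.5,
) -> Tuple[ContactMatrix, NormalizationState]:
    """Iterate M_ij <- M_ij / (w_hat_i * w_hat_j)**omega until all w_hat -> 1.

    Bins with initial trans weight below mean(w) - 3 sd(w) are excluded before
    iteration; the corrected matrix is rescaled to the input mass after
    convergence.  Non-convergence is reported on the returned state, never
    silently.  ``omega`` damps the update; the fixed point is unchanged, and
    the half-step default suppresses the slowly-decaying alternation between
    the capture classes that full steps excite on bipartite-like (bait versus
    non-bait) weight structure.
    """
    out = cm.copy()
    state = compute_weights(out)
    retained = state.retained.copy()
    w0 = state.w[retained]
    if len(w0) == 0:
        raise ValueError("all bins invalid; nothing to normalize")
    # Discard bins whose initial weight falls more than three s.d. below the
    # mean — the low-visibility bins that keep w_hat from converging and whose
    # correction amplifies counting noise.  Capture makes the weight
    # distribution a mixture of two scales (bait vs other bins) and strongly
    # right-skewed within each, so the rule is applied per capture class on
    # log-weights, where the spread is meaningful; zero-weight bins (invisible
    # in trans) are always dropped when trans information exists.
    if state.W > 0:
        drop = np.zeros(out.n_bins, dtype=bool)
        if out.enriched is not None and out.enriched.any():
            classes = [retained & out.enriched, retained & ~out.enriched]
        else:
            classes = [retained.copy()]
        for cls in classes:
            wc = state.w[cls]
            pos = wc > 0
            if pos.sum() >= 3:
                lw = np.log(wc[pos])
                cutoff = np.exp(lw.mean() - 3.0 * lw.std())
            else:
                cutoff = 0.0
            drop |= cls & (state.w < max(cutoff, np.finfo(float).tiny))
        retained = retained & ~drop
    if not retained.any():
        raise ValueError("all bins excluded by the 3-s.d. weight rule")
    if state.W == 0:
        # cis-only matrix: weights carry no information, return unchanged
        state.retained = retained
        state.converged = True
        return out, state

    input_mass = out.values.sum()
    r, c, v = out.coo(values=True)
    live = retained[r] & retained[c]
    e_mask = np.ones(len(r), dtype=bool)
    if out.enriched is not None and out.enriched.any():
        e_mask = out.enriched[r] | out.enriched[c]
    for it in range(1, max_iter + 1):
        w = np.zeros(out.n_bins)
        npop = np.zeros(out.n_bins)
        trans = out.is_trans(r, c) & live & e_mask
        np.add.at(w, r[trans], v[trans])
        np.add.at(w, c[trans], v[trans])
        nz = trans & (v > 0)
        np.add.at(npop, r[nz], 1)
        np.add.at(npop, c[nz], 1)
        W = float(w[retained].sum())
        A = float(npop[retained].sum())
        w_hat = np.ones(out.n_bins)
        ok = retained & (npop > 0)
        w_hat[ok] = (w[ok] / npop[ok]) * (A / W)
        v = np.where(live, v / (w_hat[r] ** omega * w_hat[c] ** omega), v)
        state = NormalizationState(
            w=w, n_populated=npop, W=W, A=A, w_hat=w_hat,
            retained=retained, iteration=it, tol=tol,
        )
        if state.max_deviation() <= tol:
            state.converged = True
            break
    if not state.converged:
        warnings.warn(
            f"bias correction did not converge in {max_iter} iterations "
            f"(max |w_hat - 1| = {state.max_deviation():.3g})",
            stacklevel=2,
        )
    # restore total mass; drop excluded bins from the corrected values
    v = np.where(live, v, 0.0)
    if v.sum() > 0:
        v = v * (input_mass / v.sum())
    n = out.n_bins
    out.values = sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    out.values.eliminate_zeros()
    out.valid = retained
    return out, state


@dataclass
class DistanceTemplate:
    """Smoothed expected cis contact frequency as a function of separation.

    ``distance`` is a log-spaced grid of bin-midpoint separations (bases);
    ``expected`` is the smoothed mean contact count per available bin pair at
    that separation.  ``alpha_short`` / ``alpha_long`` are log-log slopes
    fitted over the two power-law regimes.
    """

    distance: np.ndarray
    expected: np.ndarray
    alpha_short: float
    alpha_long: float
    bandwidth_decades: float = 0.1

    def interpolate(self, d: np.ndarray) -> np.ndarray:
        """Expected frequency at separations ``d`` (log-log interpolation)."""
        logd = np.log10(np.maximum(np.asarray(d, dtype=float), 1.0))
        logf = np.interp(
            logd, np.log10(self.distance), np.log10(self.expected)
        )
        return 10.0 ** logf


def _loglog_slope(d: np.ndarray, f: np.ndarray, lo: float, hi: float) -> float:
    sel = (d >= lo) & (d <= hi) & (f > 0)
    if sel.sum() < 3:
        return np.nan
    x, y = np.log10(d[sel]), np.log10(f[sel])
    return float(np.polyfit(x, y, 1)[0])


def estimate_distance_template(
    cm: ContactMatrix,
    n_grid: int = 80,
    bandwidth_decades: float = 0.1,
    fit_short: Tuple[float, float] = SHORT_RANGE,
    fit_long: Tuple[float, float] = LONG_RANGE,
) -> DistanceTemplate:
    """Build the smoothed expected-contacts-vs-distance template.

    For every cis separation k (in bins) the raw frequency is the total
    contact mass at that separation divided by the number of valid bin pairs
    at that separation (pairs with zero contacts count in the denominator).
    Frequencies are averaged onto a log-spaced grid weighted by pair counts
    and smoothed with a Gaussian kernel on log10 distance.
    """
    res = cm.grid.resolution
    r, c, v = cm.coo(values=True)
    cis = ~cm.is_trans(r, c) & cm.valid[r] & cm.valid[c]
    r, c, v = r[cis], c[cis], v[cis]
    sep = (np.abs(cm.grid.bin_start[c] - cm.grid.bin_start[r]) // res).astype(np.int64)
    max_sep = max((cm.grid.n_bins_per_chrom[ch] for ch in cm.grid.chroms), default=1) - 1
    if max_sep < 1:
        raise ValueError("no cis bin pairs available for the distance template")
    totals = np.bincount(sep, weights=v, minlength=max_sep + 1)
    pairs = np.zeros(max_sep + 1)
    for chrom in cm.grid.chroms:
        bins = cm.grid.chrom_bins(chrom)
        mask = cm.valid[bins].astype(float)
        nb = len(mask)
        if nb < 2:
            continue
        # pairs of valid bins at separation k = autocorrelation of the valid mask
        corr = np.correlate(mask, mask, mode="full")[nb:]  # k = 1 .. nb-1
        pairs[1:nb] += np.round(corr)
    sel = pairs > 0
    sel[0] = False  # diagonal carries no distance information
    # restrict support to the observed contact span: outside it f is not zero
    # but simply unobserved, and a zero-padded template would be meaningless
    nz = np.nonzero((totals > 0) & sel)[0]
    if len(nz) == 0:
        raise ValueError("no cis contacts available for the distance template")
    # the extreme separations are only partially covered by the observable
    # range and would tilt the fitted slopes; drop one boundary bin per side
    lo_k, hi_k = nz[0], nz[-1]
    if hi_k - lo_k >= 4:
        lo_k, hi_k = lo_k + 1, hi_k - 1
    sel[:lo_k] = False
    sel[hi_k + 1 :] = False
    ks = np.nonzero(sel)[0]
    if len(ks) == 0:
        raise ValueError("no cis bin pairs available for the distance template")
    d_k = ks.astype(float) * res  # bin-midpoint separation
    f_k = totals[ks] / pairs[ks]
    n_pairs = pairs[ks]

    # aggregate per-separation frequencies onto log-spaced distance bins
    # (pair-weighted), so each template point is a positive average frequency
    logd_k = np.log10(d_k)
    edges = np.linspace(logd_k.min(), logd_k.max() + 1e-9, n_grid + 1)
    which = np.clip(np.digitize(logd_k, edges) - 1, 0, n_grid - 1)
    agg_counts = np.bincount(which, weights=f_k * n_pairs, minlength=n_grid)
    agg_pairs = np.bincount(which, weights=n_pairs, minlength=n_grid)
    agg_logd = np.bincount(which, weights=logd_k * n_pairs, minlength=n_grid)
    occ = agg_pairs > 0
    f_bin = agg_counts[occ] / agg_pairs[occ]
    logd = agg_logd[occ] / agg_pairs[occ]
    w_bin = agg_pairs[occ]
    pos = f_bin > 0
    if pos.sum() < 3:
        raise ValueError("too few populated distance bins for a template")
    # Gaussian-kernel local-linear smoothing of log f on log distance: local
    # linear (not a plain weighted mean) so an exact power law stays an exact
    # line even at the boundaries of the support
    lx, ly, lw = logd[pos], np.log10(f_bin[pos]), w_bin[pos]
    grid = np.linspace(logd.min(), logd.max(), n_grid)
    fs_log = np.empty(n_grid)
    for gi, g in enumerate(grid):
        wts = np.exp(-0.5 * ((lx - g) / bandwidth_decades) ** 2) * lw
        sw = wts.sum()
        xb = (wts @ lx) / sw
        yb = (wts @ ly) / sw
        sxx = wts @ (lx - xb) ** 2
        slope = (wts @ ((lx - xb) * (ly - yb))) / sxx if sxx > 0 else 0.0
        fs_log[gi] = yb + slope * (g - xb)
    fs = 10.0 ** fs_log
    # enforce a monotone non-increasing template
    fs = np.minimum.accumulate(fs)
    dist = 10.0 ** grid
    return DistanceTemplate(
        distance=dist,
        expected=fs,
        alpha_short=_loglog_slope(dist, fs, *fit_short),
        alpha_long=_loglog_slope(dist, fs, *fit_long),
        bandwidth_decades=bandwidth_decades,
    )


def distance_normalize(
    cm: ContactMatrix,
    template: DistanceTemplate,
    coverage: Optional[np.ndarray] = None,
    lambda_cov: float = 1.0,
    eps: float = 1e-6,
) -> ContactMatrix:
    """Divide cis entries by the expected frequency at their separation.

    With per-bin capture ``coverage`` supplied, the correction applied to an
    entry is attenuated by gamma = clip((c/c_ref)**lambda_cov, eps, 1) where c
    is the interactor-side coverage and c_ref the median coverage over
    enriched bins: low-coverage interactors are penalized less, as required
    for capture data where expected counts off-target are not capture-scaled.
    Coverage attenuation is off (gamma = 1) by default, the pure Hi-C mode.
    Trans entries are unchanged.
    """
    out = cm.copy()
    r, c, v = out.coo(values=True)
    cis = ~out.is_trans(r, c)
    if not cis.any():
        return out
    sep = np.abs(out.grid.bin_start[c[cis]] - out.grid.bin_start[r[cis]]).astype(float)
    f = np.maximum(template.interpolate(np.maximum(sep, out.grid.resolution)), 1e-300)
    if coverage is None:
        corr = 1.0 / f
    else:
        ref = np.median(coverage[out.enriched]) if out.enriched.any() else np.median(coverage)
        ref = max(float(ref), eps)
        # attenuate on the less-covered side of the pair: gamma in (eps, 1],
        # gamma=1 applies the full 1/f correction, gamma->0 none at all
        cov_pair = np.minimum(coverage[r[cis]], coverage[c[cis]])
        gamma = np.clip((cov_pair / ref) ** lambda_cov, eps, 1.0)
        corr = f ** (-gamma)
    newv = v.copy()
    newv[cis] = v[cis] * corr
    n = out.n_bins
    out.values = sp.coo_matrix((newv, (r, c)), shape=(n, n)).tocsr()
    return out
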