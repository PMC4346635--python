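"""Significance of capture Hi-C interactions.

The null model for bias- and distance-normalized contact strengths is a
zero-inflated Weibull (ZIW): a point mass pi at zero (bin pairs that never
ligate) mixed with a Weibull(shape kappa, scale lam) for the positive
strengths.  To keep genuinely interacting pairs from inflating the null, the
Weibull component is fitted by maximum likelihood on the nonzero strengths at
or below their 95th percentile, with the likelihood renormalized for the
right truncation.

The upper-tail probability of a contact of strength x is

    P(x) = 1                               for x = 0
    P(x) = (1 - pi) * exp(-(x / lam)**kappa)  for x > 0,

multiple testing is adjusted by Benjamini-Hochberg q-values, and a contact is
called significant at q < 0.05 — in every library simultaneously when several
libraries are supplied.

The module also houses the combinatorial overlap test: the probability of
observing k or more elements common to three independent samples s_i of sizes
n_i drawn from nested universes S_1 in S_2 in S_3 of sizes N_i.  Under
independent sampling each element of S_1 is in all three samples with
probability p = prod(n_i / N_i), so K ~ Binomial(N_1, p); the upper tail is
evaluated in log space and reported as a "<1e-16"-style bound when it falls
below representable precision.  An exact without-replacement evaluation
(hypergeometric chain) is provided as an oracle for small universes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

__all__ = [
    "ZIWParams",
    "fit_ziw",
    "ziw_pvalue",
    "fdr_qvalues",
    "call_interactions",
    "OverlapTestResult",
    "combinatorial_overlap_pvalue",
    "overlap_pvalue_exact",
    "DEFAULT_FDR",
    "DEFAULT_MIN_SEPARATION",
]

DEFAULT_FDR = 0.05
DEFAULT_MIN_SEPARATION = 10_000  # long-range contacts only (>10 kb)
DEFAULT_MIN_NONZERO = 200


@dataclass
class ZIWParams:
    """Fitted zero-inflated Weibull null parameters."""

    pi: float              # zero-inflation mass in [0, 1]
    shape: float           # Weibull kappa (> 0; nan when undefined)
    scale: float           # Weibull lambda (> 0; nan when undefined)
    truncation_q: float = 0.95
    loglik: float = np.nan
    converged: bool = False
    n_zero: int = 0
    n_nonzero: int = 0
    se_shape: float = np.nan
    se_scale: float = np.nan


def _weibull_nll(theta: np.ndarray, x: np.ndarray, T: float) -> float:
    """Negative log-likelihood of a right-truncated Weibull at T."""
    k, lam = np.exp(theta)
    z = (x / lam) ** k
    zT = (T / lam) ** k
    if zT > 700:  # truncation mass ~ 1, renormalization vanishes
        log_trunc = 0.0
    else:
        log_trunc = np.log1p(-np.exp(-zT))
    ll = np.sum(np.log(k) - np.log(lam) + (k - 1) * (np.log(x) - np.log(lam)) - z)
    return -(ll - len(x) * log_trunc)


def fit_ziw(
    values: np.ndarray,
    truncation_q: float = 0.95,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
    compute_se: bool = False,
) -> ZIWParams:
    """Fit the zero-inflated Weibull null to non-negative contact strengths.

    pi is the observed zero fraction; (kappa, lambda) maximize the Weibull
    likelihood over the nonzero values at or below their ``truncation_q``
    quantile, renormalized for the right truncation.  Degenerate inputs
    (all-equal nonzero values) and optimizer failures raise, never silently
    succeed; an all-zero input returns pi=1 with undefined shape/scale.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("contact strengths must be non-negative")
    nz = v[v > 0]
    pi = 1.0 - len(nz) / len(v) if len(v) else 1.0
    if len(nz) == 0:
        return ZIWParams(pi=1.0, shape=np.nan, scale=np.nan,
                         truncation_q=truncation_q, converged=True,
                         n_zero=len(v), n_nonzero=0)
    if len(nz) < min_nonzero:
        raise ValueError(
            f"only {len(nz)} nonzero values; need at least {min_nonzero} for a stable fit"
        )
    if np.ptp(nz) == 0:
        raise ValueError("degenerate input: all nonzero strengths identical")
    T = float(np.quantile(nz, truncation_q))
    x = nz[nz <= T]
    # moment-based initialization via the Weibull coefficient of variation
    cv = x.std() / x.mean()
    k0 = max(cv, 1e-3) ** -1.086
    from scipy.special import gamma as gamma_fn

    l0 = x.mean() / gamma_fn(1.0 + 1.0 / k0)
    res = optimize.minimize(
        _weibull_nll, x0=np.log([k0, l0]), args=(x, T),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(f"truncated-Weibull optimization failed: {res.message}")
    k_hat, l_hat = np.exp(res.x)
    params = ZIWParams(
        pi=pi, shape=float(k_hat), scale=float(l_hat),
        truncation_q=truncation_q, loglik=-float(res.fun), converged=True,
        n_zero=int(len(v) - len(nz)), n_nonzero=int(len(nz)),
    )
    if compute_se:
        h = 1e-4
        H = np.zeros((2, 2))
        t0 = res.x

        def f(t):
            return _weibull_nll(t, x, T)

        for a in range(2):
            for b in range(2):
                ea, eb = np.eye(2)[a] * h, np.eye(2)[b] * h
                H[a, b] = (
                    f(t0 + ea + eb) - f(t0 + ea - eb) - f(t0 - ea + eb) + f(t0 - ea - eb)
                ) / (4 * h * h)
        cov_log = np.linalg.inv(H)
        # delta method back to (kappa, lambda)
        params.se_shape = float(k_hat * np.sqrt(max(cov_log[0, 0], 0.0)))
        params.se_scale = float(l_hat * np.sqrt(max(cov_log[1, 1], 0.0)))
    return params


def ziw_pvalue(x, params: ZIWParams) -> np.ndarray:
    """Upper-tail ZIW probability of a contact at least as strong as ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("strength must be non-negative")
    if not np.isfinite(params.shape):
        return np.where(x == 0, 1.0, 1.0 - params.pi)
    tail = (1.0 - params.pi) * np.exp(-((x / params.scale) ** params.shape))
    return np.where(x == 0, 1.0, tail)


def fdr_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# interaction calling
# ---------------------------------------------------------------------------

def _pair_universe(cm: ContactMatrix, min_sep: int) -> pd.DataFrame:
    """All testable bin pairs: >=1 enriched bin, both valid, long-range in cis.

    N-N pairs never enter interaction calling; the universe includes pairs
    with zero observed contacts so that the zero-inflation mass and the
    multiple-testing burden are defined over all testable pairs.
    """
    grid = cm.grid
    e_bins = np.nonzero(cm.enriched & cm.valid)[0]
    valid_bins = np.nonzero(cm.valid)[0]
    if len(e_bins) == 0:
        raise ValueError("no enriched (capture) bins; nothing to test")
    res = grid.resolution
    min_bins = int(np.floor(min_sep / res)) + 1  # bin separation strictly > min_sep/res
    rows = []
    cols = []
    for e in e_bins:
        sep = np.abs(valid_bins - e)
        same = grid.bin_chrom_code[valid_bins] == grid.bin_chrom_code[e]
        ok = (~same) | (sep >= min_bins)
        partners = valid_bins[ok]
        rows.append(np.full(len(partners), e))
        cols.append(partners)
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    pairs = pd.DataFrame({"bin_i": lo, "bin_j": hi}).drop_duplicates(ignore_index=True)
    i, j = pairs["bin_i"].to_numpy(), pairs["bin_j"].to_numpy()
    both_e = cm.enriched[i] & cm.enriched[j]
    trans = grid.bin_chrom_code[i] != grid.bin_chrom_code[j]
    context = np.where(both_e, "test", np.where(trans, "trans", "cis"))
    pairs["context"] = context
    # interactor bin: the non-enriched partner (either for E-E)
    interactor = np.where(cm.enriched[i], j, i)
    pairs["interactor"] = interactor
    return pairs


def _interval_key(cm: ContactMatrix, pairs: pd.DataFrame, window: int) -> pd.Series:
    """Fit-interval label: context, interactor chromosome and 10-Mb window."""
    grid = cm.grid
    inter = pairs["interactor"].to_numpy()
    chrom = grid.bin_chrom_code[inter]
    win = grid.bin_start[inter] // window
    key = np.where(
        pairs["context"] == "test",
        "test",
        pd.Series(pairs["context"]).str.cat(
            [pd.Series(chrom).astype(str), pd.Series(win).astype(str)], sep=":"
        ),
    )
    return pd.Series(key, index=pairs.index)


def _lookup_values(cm: ContactMatrix, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    m = cm.values.tocsr()
    return np.asarray(m[i, j]).ravel()


def call_interactions(
    matrices: Sequence[ContactMatrix],
    fdr: float = DEFAULT_FDR,
    min_sep: int = DEFAULT_MIN_SEPARATION,
    interval_window: int = 10_000_000,
    truncation_q: float = 0.95,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
) -> pd.DataFrame:
    """Call significant interactions from normalized matrices of >=1 library.

    Test-region (E-E) strengths are pooled into one ZIW fit; cis and trans
    pairs are fitted separately per interactor 10-Mb interval, intervals with
    fewer than ``min_nonzero`` nonzero strengths falling back to the pooled
    fit of their context.  Only pairs separated by more than ``min_sep`` (or
    trans) are eligible.  Returns one row per eligible pair with per-library
    strength, P and q, and ``shared_significant`` = q < ``fdr`` in every
    library.
    """
    if not matrices:
        raise ValueError("need at least one normalized matrix")
    cm0 = matrices[0]
    pairs = _pair_universe(cm0, min_sep)
    keys = _interval_key(cm0, pairs, interval_window)
    i, j = pairs["bin_i"].to_numpy(), pairs["bin_j"].to_numpy()
    out = pairs[["bin_i", "bin_j", "context"]].copy()
    sig_all = np.ones(len(pairs), dtype=bool)
    for li, cm in enumerate(matrices):
        vals = _lookup_values(cm, i, j)
        pvals = np.ones(len(pairs))
        # pooled per-context fallback fits
        pooled: Dict[str, ZIWParams] = {}
        for ctx in np.unique(pairs["context"]):
            cvals = vals[pairs["context"] == ctx]
            try:
                pooled[ctx] = fit_ziw(cvals, truncation_q, min_nonzero)
            except ValueError:
                pooled[ctx] = None
        for key in keys.unique():
            sel = (keys == key).to_numpy()
            ctx = pairs.loc[sel, "context"].iloc[0]
            gvals = vals[sel]
            try:
                params = fit_ziw(gvals, truncation_q, min_nonzero)
            except ValueError:
                params = pooled.get(ctx)
            if params is None:
                continue  # untestable interval: keep p = 1
            pvals[sel] = ziw_pvalue(gvals, params)
        qvals = fdr_qvalues(pvals)
        out[f"strength_{li}"] = vals
        out[f"p_{li}"] = pvals
        out[f"q_{li}"] = qvals
        sig_all &= qvals < fdr
    out["shared_significant"] = sig_all
    return out


def calls_to_bedpe(
    calls: pd.DataFrame, cm: ContactMatrix, path, significant_only: bool = True
) -> None:
    """Write calls as BEDPE; score is -log10 of the worst per-library q."""
    qcols = [c for c in calls.columns if c.startswith("q_")]
    df = calls[calls["shared_significant"]] if significant_only else calls
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            c1, s1, e1 = cm.grid.bin_location(int(row["bin_i"]))
            c2, s2, e2 = cm.grid.bin_location(int(row["bin_j"]))
            qworst = max(row[c] for c in qcols)
            score = -np.log10(max(qworst, 1e-300))
            name = f"{row['context']}_{int(row['bin_i'])}_{int(row['bin_j'])}"
            extra = "\t".join(f"{row[c]:.4g}" for c in df.columns if c not in
                              ("bin_i", "bin_j", "context", "shared_significant"))
            fh.write(
                f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{name}\t{score:.3f}\t.\t.\t{extra}\n"
            )


# ---------------------------------------------------------------------------
# combinatorial overlap test
# ---------------------------------------------------------------------------

@dataclass
class OverlapTestResult:
    pvalue: float          # 0.0 when below double precision; see log10_pvalue
    log10_pvalue: float
    report: str            # e.g. "P < 1e-16" for extreme tails

    def __float__(self) -> float:
        return self.pvalue


def _validate_overlap_input(k: int, n: Sequence[int], N: Sequence[int]):
    """Check invariants and reorder the (n_i, N_i) pairs so that S1 is the
    smallest universe (samples may be supplied in any order, e.g. per cell
    line)."""
    n = list(n)
    N = list(N)
    if len(n) != 3 or len(N) != 3:
        raise ValueError("three samples and three universes are required")
    if any(ni > Ni for ni, Ni in zip(n, N)):
        raise ValueError("sample size exceeds universe size")
    if k > min(n):
        raise ValueError("overlap cannot exceed the smallest sample")
    if k < 0:
        raise ValueError("overlap count must be non-negative")
    order = np.argsort(N, kind="stable")
    return [n[i] for i in order], [N[i] for i in order]


def combinatorial_overlap_pvalue(
    k: int, n: Sequence[int], N: Sequence[int]
) -> OverlapTestResult:
    """P(K >= k) for the triple overlap K ~ Binomial(N1, prod(n_i / N_i)).

    Under independent uniform sampling every element of the smallest universe
    S1 lands in all three samples with probability p = prod(n_i / N_i).
    Extreme tails are evaluated in log space; below double precision the
    report string carries the "<1e-16"-style bound.
    """
    n, N = _validate_overlap_input(k, n, N)
    if k == 0:
        return OverlapTestResult(1.0, 0.0, "P = 1")
    p = float(np.prod(np.asarray(n, dtype=float) / np.asarray(N, dtype=float)))
    logp = stats.binom.logsf(k - 1, int(N[0]), p)
    log10p = logp / np.log(10.0)
    pval = float(np.exp(logp))
    if pval == 0.0 or log10p < -16:
        report = "P < 1e-16"
    else:
        report = f"P = {pval:.3g}"
    return OverlapTestResult(pval, float(log10p), report)


def overlap_pvalue_exact(k: int, n: Sequence[int], N: Sequence[int]) -> float:
    """Exact P(K >= k) under without-replacement sampling from nested universes.

    Conditions on the hypergeometric chain: X = |s1 ∩ s2| ~ HG(N2, n1, n2)
    (since s1 ⊆ S1 ⊆ S2), then K | X ~ HG(N3, X, n3).  Serves as the
    independent oracle for the binomial approximation on small inputs.
    """
    n, N = _validate_overlap_input(k, n, N)
    if k == 0:
        return 1.0
    n1, n2, n3 = n
    N1, N2, N3 = N
    total = 0.0
    for x in range(k, min(n1, n2) + 1):
        px = stats.hypergeom.pmf(x, N2, n1, n2)
        if px == 0:
            continue
        total += px * stats.hypergeom.sf(k - 1, N3, x, n3)
    return float(min(total, 1.0))
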