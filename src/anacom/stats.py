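"""Nonparametric test kernel shared by the mapping and the task scoring.

Three tests cover everything the pipeline reports: the Wilcoxon/Mann-Whitney
rank-sum test (subregion patients vs controls, region-vs-rest contrasts),
the Wilcoxon signed-rank test (paired within-group comparisons such as
ongoing RT before vs during the prospective-memory phase), and the Pearson
chi-square for categorical covariates.

p-values come from :mod:`scipy.stats`; the z deviates mirror the rank-sum /
signed-rank normal approximations that clinical software of the study's era
printed (tie-corrected variance; continuity correction on by default for the
rank-sum test).  For small tie-free samples the exact null distribution is
used automatically, so that tiny subregions (three patients is the minimum
tested) are never judged by an asymptotic approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` is the conventionally reported value: min(U_a, U_b) for the
    rank-sum test (the convention of the clinical literature), W for the
    signed-rank test, the chi-square statistic otherwise.  The rank-sum
    result additionally exposes ``u_first``/``u_second`` because authors
    differ on which U they print.
    """

    statistic: float
    p: float
    method: str
    z: float | None = None
    u_first: float | None = None
    u_second: float | None = None
    df: int | None = None
    n1: int | None = None
    n2: int | None = None


def _rank_sum_z(a: np.ndarray, b: np.ndarray, u_min: float,
                continuity: bool) -> float:
    """Normal deviate for min-U with mid-rank tie correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    cc = 0.5 if continuity else 0.0
    dev = u_min - mu
    # shift toward zero by the continuity correction
    dev = math.copysign(max(abs(dev) - cc, 0.0), dev) if dev != 0 else 0.0
    return dev / math.sqrt(var)


def rank_sum(a, b, exact_threshold: int = 12, continuity: bool = True,
             alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of ``a`` vs ``b``.

    The exact null distribution is used when the pooled sample is tie-free
    and no larger than ``exact_threshold``; otherwise the tie-corrected
    normal approximation (continuity-corrected when ``continuity``).  The z
    deviate is always reported from the normal approximation so that exact
    and approximate results are comparable across a map.  ``alternative``
    follows scipy ('two-sided' default; 'greater' means a tends larger).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum requires non-empty samples")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and (n1 + n2) <= exact_threshold
    if use_exact:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
        method = "rank_sum_exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic",
            use_continuity=continuity,
        )
        method = "rank_sum_normal"
    u_first = float(res.statistic)
    u_second = n1 * n2 - u_first
    u_min = min(u_first, u_second)
    z = _rank_sum_z(a, b, u_min, continuity)
    return TestResult(
        statistic=u_min, p=min(float(res.pvalue), 1.0), method=method, z=z,
        u_first=u_first, u_second=u_second, n1=n1, n2=n2,
    )


def signed_rank(x, y, exact_threshold: int = 12) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (the classical convention); if every
    difference is zero the result is degenerate with p = 1.  The exact
    sign-flip distribution is used for small tie-free difference sets,
    otherwise the normal approximation.  z is the tie-corrected normal
    deviate of W without continuity correction (the form the study era's
    software printed alongside signed-rank p-values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("signed_rank requires at least 2 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p=1.0, method="signed_rank_degenerate",
                          z=0.0, n1=len(x))
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    tie_free = np.unique(np.abs(d)).size == n
    use_exact = tie_free and n <= exact_threshold
    res = sps.wilcoxon(d, alternative="two-sided",
                       method="exact" if use_exact else "approx")
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
    z = 0.0 if var <= 0 else (w_pos - mu) / math.sqrt(var)
    return TestResult(
        statistic=w, p=min(float(res.pvalue), 1.0),
        method="signed_rank_exact" if use_exact else "signed_rank_normal",
        z=z, n1=len(x),
    )


def chi_square_2xk(table) -> TestResult:
    """Pearson chi-square of independence on an r x k count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a marginal total is zero")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(stat), p=min(float(p), 1.0),
                      method="chi_square", df=int(df))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks) with its approximate p.

    A constant input makes the correlation undefined: rho is returned as NaN
    with p = NaN so callers can report the value as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman requires equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(statistic=float("nan"), p=float("nan"),
                          method="spearman", n1=len(x))
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p=float(p), method="spearman",
                      n1=len(x))
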