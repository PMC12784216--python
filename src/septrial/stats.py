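"""Nonparametric statistics battery for repeated-measures SEP summaries.

Implements the quantities the pipeline reports: SNR as |mean|/SD,
coefficient of variation, the tie-corrected Friedman test (with exact
small-sample p by full enumeration of within-row rank configurations),
Kendall's coefficient of concordance w = chi2 / (n (k - 1)) as its effect
size, the Wilcoxon signed-rank test (exact distribution by dynamic
programming up to n = 25), Holm step-down multiplicity adjustment,
a Monte-Carlo Lilliefors normality test, and the single-measurement
absolute-agreement intraclass correlation ICC(2,1) with F-based 95%
confidence intervals.

All standard deviations are sample SDs (ddof = 1) throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.stats import rankdata

__all__ = [
    "RepeatedMeasures",
    "StatResult",
    "snr_mean_std",
    "coefficient_of_variation",
    "friedman",
    "kendalls_w",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "lilliefors",
    "icc_21",
    "icc_interpretation",
]


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    statistic: float
    p_value: float
    method: str
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    n: int | None = None
    k: int | None = None
    df: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class RepeatedMeasures:
    """Subjects x conditions measurement matrix (complete rows only are tested)."""

    values: np.ndarray
    condition_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] < 2:
            raise ValueError("need at least k = 2 conditions")
        if self.condition_labels is None:
            self.condition_labels = list(range(self.values.shape[1]))

    def complete(self) -> tuple[np.ndarray, int]:
        """Rows without missing cells, plus the number of dropped rows."""
        ok = ~np.isnan(self.values).any(axis=1)
        return self.values[ok], int((~ok).sum())


def snr_mean_std(values) -> float:
    """SNR as the ratio of |mean| to the sample standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: SNR undefined")
    return float(abs(x.mean()) / sd)


def coefficient_of_variation(values) -> float:
    """CV as the ratio of the sample standard deviation to the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(x.std(ddof=1) / mean)


def _friedman_chi2_from_ranks(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from within-row midranks."""
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3.0 * n * (k + 1)
    # Standard tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1)).
    tie_sum = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    c = 1.0 - tie_sum / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return float(chi2 / c)


def friedman(rm, exact_max_n: int = 5, exact_max_k: int = 3) -> StatResult:
    """Friedman repeated-measures test with midranks and tie correction.

    For small designs (n <= 5 complete rows and k <= 3 conditions) the
    p-value is exact, by enumerating all (k!)^n equally likely within-row
    rank configurations; otherwise it comes from the chi-square(k-1)
    reference distribution.  Rows with missing cells are dropped and
    counted in ``extras['n_dropped']``.  Kendall's w is attached as the
    effect size.
    """
    if not isinstance(rm, RepeatedMeasures):
        rm = RepeatedMeasures(np.asarray(rm, dtype=float))
    x, n_dropped = rm.complete()
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least two complete rows")
    ranks = rankdata(x, axis=1)
    chi2 = _friedman_chi2_from_ranks(ranks)
    if n <= exact_max_n and k <= exact_max_k:
        perms = [np.array(list(itertools.permutations(row))) for row in ranks]
        count = total = 0
        for combo in itertools.product(*perms):
            stat = _friedman_chi2_from_ranks(np.asarray(combo))
            count += stat >= chi2 - 1e-12
            total += 1
        p = count / total
        method = "friedman-exact"
    else:
        p = float(spstats.chi2.sf(chi2, k - 1))
        method = "friedman-chi2"
    return StatResult(statistic=chi2, p_value=p, method=method,
                      effect_size=kendalls_w(chi2, n, k), n=n, k=k, df=k - 1,
                      extras={"n_dropped": n_dropped})


def kendalls_w(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance, w = chi2 / (n (k - 1)), in [0, 1]."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 subjects and k >= 2 conditions")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(min(1.0, chi2 / (n * (k - 1))))


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank sum via DP over doubled ranks.

    ``ranks2`` are the |difference| midranks doubled to integers; ``w2`` is
    the doubled observed positive-rank sum.  Under the null every sign
    pattern is equally likely, so the distribution of the positive-rank sum
    is the convolution of independent {0, r} increments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[:w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped; |differences| are midranked.  The p-value
    is exact (sign-pattern distribution by dynamic programming) up to
    ``exact_max_n`` non-zero differences, and a tie-corrected normal
    approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 3:
        raise ValueError("need at least 3 non-zero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(np.round(ranks * 2), w_plus * 2)
        method = "wilcoxon-exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts ** 3 - counts) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * spstats.norm.sf(abs(z)))
        method = "wilcoxon-normal"
    return StatResult(statistic=w_plus, p_value=min(1.0, p), method=method, n=n,
                      extras={"n_zero_dropped": int(x.size - n) if y is None else None})


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    The i-th smallest p-value is multiplied by (m - i + 1), a running
    maximum enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, np.maximum.accumulate(p[order] * np.arange(m, 0, -1)))
    out = np.empty(m)
    out[order] = adj
    return out


_LILLIEFORS_TABLES: dict[tuple[int, int], np.ndarray] = {}


def _lilliefors_d(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal fitted by moments."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = spstats.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def lilliefors(values, n_mc: int = 10000, table_seed: int = 987654321) -> StatResult:
    """Lilliefors test of composite normality with a Monte-Carlo null table.

    The null distribution of the KS distance (normal with estimated mean
    and SD) is simulated once per sample size with ``n_mc`` seeded
    replicates and cached, giving a p-value resolution of about 1/n_mc.
    The statistic is invariant under affine transforms of the data.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values")
    d = _lilliefors_d(x)
    key = (n, n_mc)
    if key not in _LILLIEFORS_TABLES:
        rng = np.random.default_rng(table_seed + n)
        sims = rng.standard_normal((n_mc, n))
        _LILLIEFORS_TABLES[key] = np.sort(
            [_lilliefors_d(row) for row in sims])
    table = _LILLIEFORS_TABLES[key]
    p = (1.0 + np.sum(table >= d)) / (n_mc + 1.0)
    return StatResult(statistic=d, p_value=float(p), method="lilliefors-mc", n=n)


def icc_21(matrix, alpha: float = 0.05) -> StatResult:
    """ICC(2,1): single-measurement, absolute-agreement, two-way model.

    ``matrix`` is subjects x sessions, complete.  The estimate is
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) from the two-way
    ANOVA decomposition (rows = subjects, columns = sessions); the
    confidence interval and p-value use the standard F-based formulas for
    the absolute-agreement single-measure coefficient.  With no
    between-subject variance the estimate is <= 0 and reported as such.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if np.isnan(x).any():
        raise ValueError("matrix must be complete (no missing cells)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = float((msr - mse) / denom) if denom != 0 else 0.0

    # Hypothesis test of ICC = 0: F = MSR / MSE with (n-1), (n-1)(k-1) df.
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        f_obs = msr / mse
        p = float(spstats.f.sf(f_obs, df1, df2))
    else:
        f_obs, p = np.inf, 0.0

    # F-based confidence interval (absolute agreement, single measure).
    if icc < 1.0 and mse > 0:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = spstats.f.ppf(1 - alpha / 2, df1, v)
        f_u = spstats.f.ppf(1 - alpha / 2, v, df1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
        ci = (float(lower), float(upper))
    else:
        ci = (1.0, 1.0) if icc >= 1.0 else (float("nan"), float("nan"))

    return StatResult(statistic=float(f_obs), p_value=p, method="icc(2,1)",
                      effect_size=icc, ci=ci, n=n, k=k, df=df1,
                      extras={"msr": float(msr), "msc": float(msc), "mse": float(mse),
                              "interpretation": icc_interpretation(icc)})


def icc_interpretation(icc: float) -> str:
    """Reliability band: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >0.9 excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"
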