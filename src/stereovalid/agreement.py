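"""Agreement and group-comparison statistics for method-validation studies.

Implements the two-way absolute-agreement intraclass correlation for single
measurements — ICC(A,1) in the McGraw & Wong taxonomy, the "two-way mixed,
absolute agreement" ICC of standard statistics packages — together with
one-way ANOVA, the pooled two-sample t test, a signed hemispheric asymmetry
index, and multiple-comparison adjustment.

With the two-way decomposition of an n-subjects x k-raters table into mean
squares for rows (MSR), columns (MSC) and error (MSE):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

The same mean-squares formula serves the two-way random case; the mixed vs
random choice affects interpretation and CI labelling only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateTableError(ValueError):
    """Ratings table has no between-subject variance — ICC undefined."""


@dataclass
class ICCResult:
    icc: float
    msr: float
    msc: float
    mse: float
    ci_lower: float
    ci_upper: float
    n: int
    k: int


@dataclass
class GroupTestResult:
    """Result of a one-way group comparison (F or t)."""

    statistic: float
    statistic_name: str
    df: tuple[float, float] | float
    pvalue: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    p_adjusted: Optional[float] = None
    degenerate: bool = False


def _validate_table(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings table must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table contains missing or non-finite cells")
    return x


def two_way_mean_squares(table) -> tuple[float, float, float, int, int]:
    """Mean squares (MSR, MSC, MSE) of the two-way subjects x raters layout."""
    x = _validate_table(table)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_absolute_agreement(table, confidence: float = 0.95) -> ICCResult:
    """Two-way absolute-agreement single-measure ICC with an F-based CI.

    Values in the table are measurements of the same quantity by k methods on
    n subjects (volumes here, so all positive); systematic offsets between
    methods count against agreement through the MSC term.  The confidence
    interval uses the F-distribution approximation with Satterthwaite
    degrees of freedom.
    """
    msr, msc, mse, n, k = two_way_mean_squares(table)
    if msr <= 0 or np.isclose(msr, 0.0):
        raise DegenerateTableError(
            "no between-subject variance: ICC is undefined for this table"
        )
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    # the sample estimate can fall below -1 for pathological anti-agreement
    # tables; it is reported unclipped so it stays a pure function of the
    # mean squares (the population quantity is bounded by -1/(k-1))
    icc = float((msr - mse) / denom)

    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        lower = upper = icc  # perfect agreement: CI collapses
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a):
            lower = upper = icc
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lower = (n * (msr - f_l * mse)) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = (n * (f_u * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
    lower = float(min(max(lower, -1.0), icc))
    upper = float(min(max(upper, icc), 1.0))
    return ICCResult(icc=icc, msr=msr, msc=msc, mse=mse,
                     ci_lower=lower, ci_upper=upper, n=n, k=k)


def _group_summaries(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    means = (float(a.mean()), float(b.mean()))
    sds = (float(a.std(ddof=1)), float(b.std(ddof=1)))
    return a, b, means, sds


def anova_between(values_a: Sequence[float], values_b: Sequence[float]) -> GroupTestResult:
    """One-way fixed-effects ANOVA for two groups: F on df (1, n_a + n_b - 2).

    For two groups F equals the square of the pooled-variance t statistic.
    Zero within-group variance with unequal means yields F = inf, p = 0,
    flagged degenerate.
    """
    a, b, means, sds = _group_summaries(values_a, values_b)
    na, nb = len(a), len(b)
    grand = np.concatenate([a, b]).mean()
    ssb = na * (means[0] - grand) ** 2 + nb * (means[1] - grand) ** 2
    ssw = np.sum((a - means[0]) ** 2) + np.sum((b - means[1]) ** 2)
    df = (1.0, float(na + nb - 2))
    if ssw == 0.0:
        if ssb == 0.0:
            return GroupTestResult(0.0, "F", df, 1.0, means, sds)
        return GroupTestResult(np.inf, "F", df, 0.0, means, sds, degenerate=True)
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(f, *df))
    return GroupTestResult(float(f), "F", df, p, means, sds)


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> GroupTestResult:
    """Pooled-variance two-sample t test, two-sided."""
    a, b, means, sds = _group_summaries(values_a, values_b)
    na, nb = len(a), len(b)
    df = float(na + nb - 2)
    ssw = np.sum((a - means[0]) ** 2) + np.sum((b - means[1]) ** 2)
    if ssw == 0.0:
        if means[0] == means[1]:
            return GroupTestResult(0.0, "t", df, 1.0, means, sds)
        stat = np.inf if means[0] > means[1] else -np.inf
        return GroupTestResult(stat, "t", df, 0.0, means, sds, degenerate=True)
    pooled = ssw / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = (means[0] - means[1]) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupTestResult(float(t), "t", df, p, means, sds)


def asymmetry_index(left, right):
    """Signed left-right asymmetry as a percentage of the mean volume.

    ``100 * (L - R) / ((L + R) / 2)`` — positive when the left structure is
    larger; bounded in (-200, 200) for positive volumes.  Accepts scalars or
    arrays.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("asymmetry index requires positive volumes")
    out = 100.0 * (left - right) / ((left + right) / 2.0)
    return float(out) if out.ndim == 0 else out


def adjust_pvalues(pvals: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-comparison adjustment (Bonferroni default, Holm available)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]
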