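"""Cohort-table statistics: t tests, chi-square with cell comparisons,
one-way ANOVA with Bonferroni post hoc, Pearson correlation, Cronbach's
alpha, and LOWESS age-trend smoothing.

The two-sample t tests operate on summary statistics (n, mean, SD) so
that published cohort tables can be fed in directly; the pooled variant
reports integer df n1+n2-2, the Welch variant the fractional
Welch-Satterthwaite df.  All p-values are two-sided and unadjusted
unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError, DegenerateDataError


@dataclass(frozen=True)
class TwoSampleSummary:
    """n, mean and sample SD of one group (any unit)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateDataError("summary needs n >= 2")
        if self.sd < 0:
            raise DegenerateDataError("sd must be >= 0")


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


class PairwiseComparison(NamedTuple):
    i: int
    j: int
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


def summarize(sample: Sequence[float]) -> TwoSampleSummary:
    """Reduce a raw sample to the (n, mean, sd) summary the t tests use."""
    arr = np.asarray(sample, dtype=float)
    return TwoSampleSummary(n=len(arr), mean=float(arr.mean()),
                            sd=float(arr.std(ddof=1)))


def t_test_from_summary(a: TwoSampleSummary, b: TwoSampleSummary,
                        variant: str = "pooled") -> TTestResult:
    """Two-sample t test from group summaries.

    pooled: t = (m1-m2) / (s_p * sqrt(1/n1 + 1/n2)), df = n1+n2-2.
    welch:  t = (m1-m2) / sqrt(s1^2/n1 + s2^2/n2), fractional df by
    Welch-Satterthwaite.  p is two-sided from the t distribution.
    """
    diff = a.mean - b.mean
    v1, v2 = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if variant == "pooled":
        pooled_var = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) \
            / (a.n + b.n - 2)
        se = np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
    elif variant == "welch":
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (a.n - 1) + v2 ** 2 / (b.n - 1))
    else:
        raise ConfigError(f"unknown t-test variant {variant!r}")
    if se == 0:
        raise DegenerateDataError("zero variance in both groups: t undefined")
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def chi_square(table: np.ndarray | Sequence[Sequence[int]],
               correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on an r x c contingency table.

    No continuity correction by default.  Adjusted standardized
    residuals (O-E) / sqrt(E (1 - row/n)(1 - col/n)) are returned per
    cell; |residual| > 1.96 marks the cells driving the association
    (the table-footnote "cell comparison").
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateDataError("contingency table must be at least 2 x 2")
    if (obs < 0).any():
        raise DegenerateDataError("negative counts")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise DegenerateDataError("zero row or column margin")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=correction)
    n = obs.sum()
    row_frac = obs.sum(axis=1, keepdims=True) / n
    col_frac = obs.sum(axis=0, keepdims=True) / n
    adj = (obs - expected) / np.sqrt(
        expected * (1 - row_frac) * (1 - col_frac))
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p),
                           expected=expected, adjusted_residuals=adj)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Between-subjects one-way ANOVA over k independent samples."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise DegenerateDataError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in arrays):
        raise DegenerateDataError(
            "zero within-group variance everywhere: F undefined")
    F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n - k,
                       p=float(p))


def bonferroni_posthoc(groups: Sequence[Sequence[float]],
                       alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise pooled t tests with Bonferroni-adjusted p-values.

    Adjusted p = raw p times the number of comparisons, capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            t, p = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
            p_adj = min(1.0, float(p) * m)
            out.append(PairwiseComparison(
                i=i, j=j, t=float(t), p_raw=float(p), p_adjusted=p_adj,
                significant=p_adj < alpha))
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cronbach_alpha(items: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Cronbach's alpha over a cases x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of case
    totals), with sample (n-1) variances.  In this pipeline the items
    are the three central electrodes (C3, Cz, C4) and the cases are
    participants, computed per band on absolute power.
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise DegenerateDataError("need >= 3 cases and >= 2 items")
    if np.isnan(m).any():
        raise DegenerateDataError("missing cells in the item matrix")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def lowess_trend(x: Sequence[float], y: Sequence[float],
                 fraction: float = 0.3) -> np.ndarray:
    """LOWESS (tricube-weighted local linear) smoother.

    Returns an (n, 2) array of (sorted x, smoothed y), the age-trend
    curve drawn through band power versus age.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise DegenerateDataError("need >= 5 points")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    return lowess(y, x, frac=fraction, return_sorted=True)
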