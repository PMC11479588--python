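"""Condition-comparison statistics with normality gating.

Paired comparisons use a Shapiro-Wilk gate on the differences to choose a
paired t-test or a Wilcoxon signed-rank test; the three-condition design
uses a one-way within-subjects (repeated measures) ANOVA with Tukey HSD on
the condition means using the within-subjects error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PairedComparison:
    label_a: str
    label_b: str
    test_name: str
    statistic: float
    p: float
    n: int
    normality_p: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class TukeyPair:
    cond_a: str
    cond_b: str
    mean_diff: float
    q: float
    p: float


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    tukey: tuple[TukeyPair, ...] = field(default_factory=tuple)


def normality_gated_paired_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> PairedComparison:
    """Paired t-test or Wilcoxon signed-rank on paired samples, gated by
    Shapiro-Wilk normality of the differences (two-sided)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples must have equal length >= 3")
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("degenerate: paired differences have zero variance")
    _, sw_p = stats.shapiro(d)
    if sw_p > alpha:
        statistic, p = stats.ttest_rel(x, y)
        name = "paired t"
    else:
        statistic, p = stats.wilcoxon(x, y)
        name = "Wilcoxon signed-rank"
    return PairedComparison(
        label_a=label_a, label_b=label_b, test_name=name,
        statistic=float(statistic), p=float(p), n=int(x.size),
        normality_p=float(sw_p), mean_a=float(x.mean()), mean_b=float(y.mean()),
    )


def welch_two_sample_test(a: Sequence[float], b: Sequence[float],
                          equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test (Welch by default; pooled variance behind the flag)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=equal_var)
    return float(t), float(p)


def rm_anova_tukey(table: pd.DataFrame, correction: str | None = None) -> RMAnovaResult:
    """One-way repeated measures ANOVA (rows = experiments, columns =
    conditions) with Tukey HSD post hoc on the condition means.

    Sums of squares are partitioned into condition, subject and residual
    terms; F = MS_condition / MS_error with df (k-1, (k-1)(n-1)).  Tukey HSD
    uses the studentized-range distribution with the within-subjects error
    df.  ``correction='gg'`` applies the Greenhouse-Geisser epsilon to the
    degrees of freedom of the p-value.
    """
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = df.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 experiments")
    X = df.to_numpy(dtype=float)
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    d1, d2 = float(df_effect), float(df_error)
    if correction == "gg":
        d1 *= (eps := _gg_epsilon(X))
        d2 *= eps
    if ms_err > 0:
        F = ms_cond / ms_err
        p = float(stats.f.sf(F, d1, d2))
    elif ms_cond == 0:  # identical columns after subject centering
        F, p = 0.0, 1.0
    else:
        F, p = float("inf"), 0.0

    pairs = []
    means = X.mean(axis=0)
    se = np.sqrt(ms_err / n) if ms_err > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            q = abs(diff) / se if se > 0 else 0.0
            p_q = float(stats.studentized_range.sf(q, k, df_error)) if se > 0 else 1.0
            pairs.append(
                TukeyPair(str(df.columns[i]), str(df.columns[j]),
                          float(diff), float(q), p_q)
            )
    return RMAnovaResult(F=float(F), df_effect=df_effect, df_error=df_error,
                         p=p, tukey=tuple(pairs))


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    J = np.eye(k) - np.ones((k, k)) / k
    Sc = J @ S @ J
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    return float(num / den) if den > 0 else 1.0


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product-moment correlation with two-sided t-approximation p.

    Returns (r, p, df) with df = n - 2.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), int(a.size - 2)
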