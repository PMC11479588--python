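"""Phase-constancy analysis: phase-vs-temperature slopes and group tests.

For each experiment the mean phase of every event (PD OFF, LP ON, LP OFF,
PY ON, PY OFF) at each holding temperature is fitted with an ordinary
least-squares line; across experiments the slopes are tested against zero
with a Shapiro-Wilk normality gate choosing a one-sample t-test or a
Wilcoxon signed-rank test, Bonferroni-corrected for the battery (default
10 tests = 5 phases x 2 conditions).  A negative slope is a phase advance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SlopeFit:
    phase_event: str
    slope_per_C: float
    slope_per_10C: float
    intercept: float
    n_temps: int
    slope_se: float = float("nan")


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n: int
    normality_p: float
    n_tests: int


def fit_phase_slope(
    temps: Sequence[float],
    phases: Sequence[float],
    phase_event: str = "",
) -> SlopeFit:
    """OLS line of mean phase on temperature (slope in 1/°C and per 10 °C)."""
    T = np.asarray(temps, dtype=float)
    p = np.asarray(phases, dtype=float)
    keep = np.isfinite(T) & np.isfinite(p)
    T, p = T[keep], p[keep]
    if T.size < 2:
        raise ValueError("need >= 2 temperatures with a defined mean phase")
    slope, intercept = np.polyfit(T, p, 1)
    n = T.size
    if n > 2:
        resid = p - (slope * T + intercept)
        s2 = resid @ resid / (n - 2)
        se = float(np.sqrt(s2 / np.sum((T - T.mean()) ** 2)))
    else:
        se = float("nan")
    return SlopeFit(
        phase_event=phase_event,
        slope_per_C=float(slope),
        slope_per_10C=float(10.0 * slope),
        intercept=float(intercept),
        n_temps=int(n),
        slope_se=se,
    )


def group_slope_test(
    slopes: Sequence[float],
    n_tests: int = 10,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Test whether per-experiment slopes depart from zero.

    Shapiro-Wilk at ``alpha`` on the slopes selects a two-sided one-sample
    t-test (normal) or Wilcoxon signed-rank test (non-normal); the p-value
    is Bonferroni-adjusted by ``n_tests``.
    """
    x = np.asarray(slopes, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 slopes")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: all slopes identical (zero variance)")
    sw_stat, sw_p = stats.shapiro(x)
    if sw_p > alpha:
        t_stat, p_raw = stats.ttest_1samp(x, 0.0)
        name = "one-sample t"
        statistic = float(t_stat)
    else:
        w_stat, p_raw = stats.wilcoxon(x)
        name = "Wilcoxon signed-rank"
        statistic = float(w_stat)
    return GroupTestResult(
        test_name=name,
        statistic=statistic,
        p_raw=float(p_raw),
        p_adjusted=float(min(1.0, p_raw * n_tests)),
        n=int(x.size),
        normality_p=float(sw_p),
        n_tests=int(n_tests),
    )
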