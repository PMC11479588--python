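"""Temperature annotation, holding windows, steady-state means and Q10 fits.

The temperature sensitivity of the rhythm is summarised by the Q10 of its
frequency, f(T) = f_ref * Q10**((T - T_ref)/10).  The fit is ordinary least
squares of ln f on (T - T_ref)/10 over all holding temperatures; the
two-point endpoint estimator (f2/f1)**(10/(T2-T1)) is provided alongside for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bursts import Cycle, PHASE_EVENTS, compute_phases
from .io import TemperatureTrace


@dataclass(frozen=True)
class HoldingWindow:
    """Maximal contiguous run of cycles within tolerance of one target °C."""

    target_temp: float
    start_index: int
    stop_index: int  # exclusive
    mean_temp: float
    n_cycles: int


@dataclass(frozen=True)
class Q10Fit:
    f_ref: float
    Q10: float
    T_ref: float
    residual_sd: float
    n_points: int
    log_slope_se: float = float("nan")


def _trace_cumint(trace: TemperatureTrace) -> np.ndarray:
    t, v = trace.times, trace.values
    seg = np.diff(t) * (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[0.0], np.cumsum(seg)])


def annotate_temperature(cycles: Sequence[Cycle], trace: TemperatureTrace) -> None:
    """Attach to each cycle its time-averaged temperature.

    The trace is treated as piecewise linear; the cycle temperature is the
    exact integral mean over [start, end) (equivalently the trapezoid over
    the trace's native samples inside the cycle plus interpolated
    endpoints).  Cycles outside the trace span use nearest-sample
    extrapolation with a warning.
    """
    if len(trace) == 0:
        raise ValueError("empty temperature trace")
    t, v = trace.times, trace.values
    cum = _trace_cumint(trace)

    def integral_at(x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, t[0], t[-1])
        idx = np.clip(np.searchsorted(t, xc, side="right") - 1, 0, t.size - 2)
        vi = np.interp(xc, t, v)
        base = cum[idx] + (xc - t[idx]) * (v[idx] + vi) / 2.0
        # constant extrapolation beyond the span
        return base + np.where(x > t[-1], (x - t[-1]) * v[-1], 0.0) + np.where(
            x < t[0], (x - t[0]) * v[0], 0.0
        )

    starts = np.array([c.start for c in cycles])
    ends = np.array([c.end for c in cycles])
    if starts.size and (starts[0] < t[0] or ends[-1] > t[-1]):
        warnings.warn(
            "cycles extend past the temperature trace; using nearest-sample "
            "extrapolation", stacklevel=2,
        )
    means = (integral_at(ends) - integral_at(starts)) / (ends - starts)
    for c, m in zip(cycles, means):
        c.temperature = float(m)


def find_holding_windows(
    cycles: Sequence[Cycle],
    targets: Sequence[float],
    tolerance: float = 0.3,
    min_cycles: int = 10,
) -> list[HoldingWindow]:
    """Maximal contiguous runs of cycles within ``tolerance`` of each target.

    A cycle eligible for two targets is assigned to the nearer one.  Runs
    shorter than ``min_cycles`` are discarded (grazing transits during
    ramps).  Targets with no window are simply absent, with a warning.
    """
    targets = np.asarray(sorted(set(float(t) for t in targets)))
    temps = np.array([c.temperature for c in cycles], dtype=float)
    if np.any(np.isnan(temps)):
        raise ValueError("cycles must be temperature-annotated first")
    dist = np.abs(temps[:, None] - targets[None, :])
    nearest = np.argmin(dist, axis=1)
    in_band = dist[np.arange(temps.size), nearest] <= tolerance
    label = np.where(in_band, nearest, -1)

    windows: list[HoldingWindow] = []
    i = 0
    while i < temps.size:
        j = i
        while j < temps.size and label[j] == label[i]:
            j += 1
        if label[i] >= 0 and (j - i) >= min_cycles:
            windows.append(
                HoldingWindow(
                    target_temp=float(targets[label[i]]),
                    start_index=i,
                    stop_index=j,
                    mean_temp=float(np.mean(temps[i:j])),
                    n_cycles=j - i,
                )
            )
        i = j
    found = {w.target_temp for w in windows}
    for tgt in targets:
        if float(tgt) not in found:
            warnings.warn(f"no holding window found for target {tgt} °C", stacklevel=2)
    return windows


def steady_state_means(
    cycles: Sequence[Cycle], windows: Sequence[HoldingWindow]
) -> pd.DataFrame:
    """Per-target means/SDs of frequency and phases over holding-window cycles.

    Multiple windows at one target (e.g. the return to 11 °C) pool into one
    row.  Returns a DataFrame indexed by target temperature with columns
    ``mean_temp``, ``mean_freq``, ``sd_freq``, ``n`` and ``mean_<event>``
    for each phase event.
    """
    if not windows:
        raise ValueError("no holding windows")
    rows = {}
    for w in sorted(windows, key=lambda w: w.target_temp):
        members = list(range(w.start_index, w.stop_index))
        rows.setdefault(w.target_temp, []).extend(members)
    records = []
    for target, idx in rows.items():
        freqs = np.array([cycles[i].frequency for i in idx])
        temps = np.array([cycles[i].temperature for i in idx])
        rec = {
            "target_temp": target,
            "mean_temp": temps.mean(),
            "mean_freq": freqs.mean(),
            "sd_freq": freqs.std(ddof=1) if freqs.size > 1 else 0.0,
            "n": freqs.size,
        }
        phases = [compute_phases(cycles[i]) for i in idx]
        for ev in PHASE_EVENTS + ("pd_duration", "lp_duty"):
            vals = np.array([getattr(p, ev) for p in phases
                             if getattr(p, ev) is not None], dtype=float)
            rec[f"mean_{ev}"] = vals.mean() if vals.size else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("target_temp").sort_index()


def fit_q10(temps: Sequence[float], freqs: Sequence[float], T_ref: float = 11.0) -> Q10Fit:
    """Least-squares fit of ln f against (T - T_ref)/10.

    Q10 = exp(slope), f_ref = exp(intercept); residual_sd is the log-space
    residual standard deviation (0 with <= 2 points).
    """
    T = np.asarray(temps, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if T.size != f.size or T.size < 2:
        raise ValueError("need >= 2 (T, f) points")
    if np.any(f <= 0):
        raise ValueError("all frequencies must be > 0")
    x = (T - T_ref) / 10.0
    y = np.log(f)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    n = T.size
    residual_sd = float(np.sqrt(resid @ resid / (n - 2))) if n > 2 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = residual_sd / np.sqrt(sxx) if n > 2 and sxx > 0 else float("nan")
    return Q10Fit(
        f_ref=float(np.exp(intercept)),
        Q10=float(np.exp(slope)),
        T_ref=float(T_ref),
        residual_sd=residual_sd,
        n_points=int(n),
        log_slope_se=se,
    )


def endpoint_q10(f1: float, T1: float, f2: float, T2: float) -> float:
    """Two-point Q10 estimator (f2/f1)**(10/(T2 - T1))."""
    if f1 <= 0 or f2 <= 0:
        raise ValueError("frequencies must be > 0")
    if T1 == T2:
        raise ValueError("temperatures must differ")
    return float((f2 / f1) ** (10.0 / (T2 - T1)))


def condition_difference(
    means_a: pd.DataFrame, means_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-target frequency differences (a minus b) plus within-condition changes.

    Both tables must share the target-temperature grid (rows of
    :func:`steady_state_means`).  The returned frame has the per-target
    difference; its ``attrs['change_a']``/``attrs['change_b']`` carry the
    within-condition top-minus-bottom frequency change (e.g. 21 °C - 11 °C).
    """
    ia, ib = set(means_a.index), set(means_b.index)
    if ia != ib:
        missing = sorted(ia.symmetric_difference(ib))
        raise ValueError(f"temperature grids differ; unmatched targets: {missing}")
    a = means_a.sort_index()
    b = means_b.sort_index()
    out = pd.DataFrame(
        {
            "freq_a": a["mean_freq"],
            "freq_b": b["mean_freq"],
            "difference": a["mean_freq"] - b["mean_freq"],
        }
    )
    lo, hi = a.index.min(), a.index.max()
    out.attrs["change_a"] = float(a.loc[hi, "mean_freq"] - a.loc[lo, "mean_freq"])
    out.attrs["change_b"] = float(b.loc[hi, "mean_freq"] - b.loc[lo, "mean_freq"])
    return out
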