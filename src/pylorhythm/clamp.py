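"""Voltage-clamp quantification of the hyperpolarization-activated current.

I_h activates slowly during a long hyperpolarizing step, so its amplitude
is measured as the difference between the holding current shortly after the
step onset (after a capacitive-transient exclusion delay) and the holding
current at steady state near the end of the step.  Percent block across
conditions is the mean of per-cell reductions, never the ratio of group
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ClampTrace:
    """Uniformly sampled current trace (nA) around one voltage step."""

    times: np.ndarray
    current: np.ndarray
    step_onset: float
    step_duration: float
    holding_V: float | None = None
    step_V: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", i)
        if t.size != i.size or t.size < 2:
            raise ValueError("times and current must have equal length >= 2")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        if t[0] > self.step_onset or t[-1] < self.step_onset + self.step_duration:
            raise ValueError("trace must span the whole voltage step")


@dataclass(frozen=True)
class IhMeasure:
    I_initial: float
    I_steady: float
    I_h: float
    initial_window: tuple[float, float]
    steady_window: tuple[float, float]


def measure_ih(
    trace: ClampTrace,
    initial_window: tuple[float, float] | None = None,
    steady_window: tuple[float, float] | None = None,
) -> IhMeasure:
    """I_h amplitude = |mean current in steady window - mean in initial window|.

    Windows are (start, stop) in trace time.  Defaults: the initial window is
    50-150 ms after the step onset (excluding the capacitive transient) and
    the steady window is the last 1 s of the step.  Both must lie inside the
    step and contain at least 5 samples.
    """
    on = trace.step_onset
    off = trace.step_onset + trace.step_duration
    if initial_window is None:
        initial_window = (on + 0.050, on + 0.150)
    if steady_window is None:
        steady_window = (off - 1.0, off)
    for name, (lo, hi) in (("initial", initial_window), ("steady", steady_window)):
        if lo < on or hi > off or hi <= lo:
            raise ValueError(f"{name} window must lie inside the step")

    def window_mean(lo: float, hi: float, name: str) -> float:
        sel = (trace.times >= lo) & (trace.times <= hi)
        if sel.sum() < 5:
            raise ValueError(f"fewer than 5 samples in {name} window")
        return float(trace.current[sel].mean())

    i0 = window_mean(*initial_window, "initial")
    iss = window_mean(*steady_window, "steady")
    return IhMeasure(
        I_initial=i0,
        I_steady=iss,
        I_h=abs(iss - i0),
        initial_window=tuple(initial_window),
        steady_window=tuple(steady_window),
    )


def percent_block(
    ih_control: Sequence[float], ih_blocked: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """Per-cell percent reduction of I_h and its group mean ± SD.

    reduction_i = 100 * (1 - blocked_i / control_i); the group statistic is
    the mean of the per-cell reductions (mean of ratios), which differs from
    the ratio of group means when amplitudes vary across cells.
    """
    c = np.asarray(ih_control, dtype=float)
    b = np.asarray(ih_blocked, dtype=float)
    if c.size != b.size or c.size == 0:
        raise ValueError("paired per-cell values required")
    if np.any(c <= 0):
        bad = np.flatnonzero(c <= 0)
        raise ValueError(f"control I_h must be > 0 (cells {bad.tolist()})")
    per_cell = 100.0 * (1.0 - b / c)
    sd = float(per_cell.std(ddof=1)) if per_cell.size > 1 else 0.0
    return per_cell, float(per_cell.mean()), sd
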