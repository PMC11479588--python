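"""Smoothing and classification of per-cycle frequency/temperature dynamics.

Quantifies the non-monotonic "jag": cycles are labelled by whether the
smoothed temperature rose by more than 0.01 °C/cycle and whether the
smoothed frequency changed by more than 0.002 Hz/cycle, and the statistic
is the conditional probability of a frequency decrease given a temperature
increase (and of a frequency increase given temperature stability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TEMP_STATES = ("increasing", "stable")
FREQ_STATES = ("increasing", "decreasing", "stable")


@dataclass(frozen=True)
class JagStats:
    p_dec_given_inc: float | None
    p_inc_given_stable: float | None
    n_inc: int
    n_stable: int
    n_dec_in_inc: int
    n_inc_in_stable: int


def smooth_series(values: Sequence[float], window: int, *, mode: str = "centered") -> np.ndarray:
    """Moving average over ``window`` cycles.

    ``mode='centered'`` (default) truncates the window symmetrically at the
    edges so the output has the input's length (an even window takes the
    extra sample from the past); ``mode='trailing'`` averages the current
    and preceding ``window - 1`` samples.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("centered", "trailing"):
        raise ValueError("mode must be 'centered' or 'trailing'")
    s = pd.Series(np.asarray(values, dtype=float))
    if s.size < 1:
        raise ValueError("need at least one value")
    center = mode == "centered"
    return s.rolling(window, center=center, min_periods=1).mean().to_numpy()


def classify_cycles(
    smoothed_temp: Sequence[float],
    smoothed_freq: Sequence[float],
    temp_thr: float = 0.01,
    freq_thr: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each cycle's temperature and frequency state.

    For cycle i >= 1, Δ = series[i] - series[i-1].  Temperature is
    ``increasing`` iff Δtemp > temp_thr (strictly), else ``stable``;
    frequency is ``decreasing`` iff Δfreq < -freq_thr, ``increasing`` iff
    Δfreq > freq_thr, else ``stable``.  The first cycle has no difference
    and is left unclassified (None).
    """
    st = np.asarray(smoothed_temp, dtype=float)
    sf = np.asarray(smoothed_freq, dtype=float)
    if st.size != sf.size:
        raise ValueError("temperature and frequency series lengths differ")
    if st.size < 2:
        raise ValueError("need at least 2 cycles to classify")
    if temp_thr <= 0 or freq_thr <= 0:
        raise ValueError("thresholds must be > 0")
    dt = np.diff(st)
    df = np.diff(sf)
    temp_state = np.where(dt > temp_thr, "increasing", "stable").astype(object)
    freq_state = np.where(
        df < -freq_thr, "decreasing", np.where(df > freq_thr, "increasing", "stable")
    ).astype(object)
    none = np.array([None], dtype=object)
    return np.concatenate([none, temp_state]), np.concatenate([none, freq_state])


def jag_probabilities(temp_states: Sequence, freq_states: Sequence) -> JagStats:
    """Conditional probabilities of frequency change given temperature state.

    An empty conditioning set yields an absent (None) probability rather
    than 0/0.
    """
    ts = np.asarray(temp_states, dtype=object)
    fs = np.asarray(freq_states, dtype=object)
    if ts.size != fs.size:
        raise ValueError("state sequences differ in length")
    ok = ts != None  # noqa: E711  (elementwise None test)
    if not np.any(ok):
        raise ValueError("no classified cycles")
    ts, fs = ts[ok], fs[ok]
    inc = ts == "increasing"
    stable = ts == "stable"
    n_inc = int(inc.sum())
    n_stable = int(stable.sum())
    n_dec_in_inc = int(np.sum(fs[inc] == "decreasing"))
    n_inc_in_stable = int(np.sum(fs[stable] == "increasing"))
    return JagStats(
        p_dec_given_inc=n_dec_in_inc / n_inc if n_inc else None,
        p_inc_given_stable=n_inc_in_stable / n_stable if n_stable else None,
        n_inc=n_inc,
        n_stable=n_stable,
        n_dec_in_inc=n_dec_in_inc,
        n_inc_in_stable=n_inc_in_stable,
    )
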