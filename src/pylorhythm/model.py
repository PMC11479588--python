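"""Statsmodels-style front end: a model built from one experiment whose
``fit`` runs the whole single-experiment analysis chain.

``ThermalResponseModel`` wraps an :class:`~pylorhythm.io.ExperimentRecord`
and a :class:`~pylorhythm.config.RunConfig`; ``fit()`` returns a
``ThermalResponseResults`` carrying the per-cycle table, holding windows,
steady-state means, the Q10 fit (with its log-space uncertainty), the jag
statistics and the phase-vs-temperature slopes, plus ``summary()`` and
quick-look plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as _b
from . import jags as _j
from . import phase as _p
from . import thermal as _t
from .config import RunConfig
from .io import (ExperimentRecord, read_spike_trains, read_temperature,
                 write_cycle_table)

PHASE_LABELS = {
    "pd_off": "PD OFF", "lp_on": "LP ON", "lp_off": "LP OFF",
    "py_on": "PY ON", "py_off": "PY OFF",
}


class ThermalResponseModel:
    """Temperature response of one pyloric-rhythm recording.

    Parameters
    ----------
    experiment : ExperimentRecord
        Spike trains (PD required; LP/PY optional) plus the temperature
        trace.
    config : RunConfig, optional
        Analysis thresholds; defaults follow the standard protocol.
    """

    def __init__(self, experiment: ExperimentRecord, config: RunConfig | None = None):
        self.experiment = experiment
        self.config = config or RunConfig()
        experiment.require_pd()

    @classmethod
    def from_files(
        cls,
        spikes_path: str | Path,
        temperature_path: str | Path,
        condition: str = "saline",
        config: RunConfig | None = None,
        **metadata,
    ) -> "ThermalResponseModel":
        trains = read_spike_trains(spikes_path)
        trace = read_temperature(temperature_path)
        rec = ExperimentRecord(condition, trains, trace, dict(metadata))
        return cls(rec, config)

    def fit(self) -> "ThermalResponseResults":
        cfg = self.config
        exp = self.experiment

        pd_bursts = _b.detect_bursts(
            exp.require_pd(), cfg.burst_min_spikes, cfg.burst_min_gap
        )
        cycles = _b.build_cycles(pd_bursts)
        followers = {
            unit: _b.detect_bursts(exp.trains[unit], cfg.burst_min_spikes, cfg.burst_min_gap)
            for unit in ("LP", "PY")
            if unit in exp.trains
        }
        assignment = _b.assign_events(cycles, followers)
        _t.annotate_temperature(cycles, exp.temperature)

        phases = [_b.compute_phases(c) for c in cycles]
        table = pd.DataFrame(
            {
                "start_s": [c.start for c in cycles],
                "period_s": [c.period for c in cycles],
                "freq_hz": [c.frequency for c in cycles],
                "temp_c": [c.temperature for c in cycles],
            }
        )
        for ev in _b.PHASE_EVENTS:
            table[f"{ev}_phase"] = [
                np.nan if getattr(p, ev) is None else getattr(p, ev) for p in phases
            ]
        table["pd_duration_s"] = [p.pd_duration for p in phases]
        table["lp_duty"] = [
            np.nan if p.lp_duty is None else p.lp_duty for p in phases
        ]

        sm_freq = _j.smooth_series(table["freq_hz"], cfg.freq_smooth_window)
        sm_temp = _j.smooth_series(table["temp_c"], cfg.temp_smooth_window)
        temp_state, freq_state = _j.classify_cycles(
            sm_temp, sm_freq, cfg.temp_increase_threshold, cfg.freq_change_threshold
        )
        table["temp_state"] = pd.array(
            [s if s is not None else pd.NA for s in temp_state], dtype="string"
        )
        table["freq_state"] = pd.array(
            [s if s is not None else pd.NA for s in freq_state], dtype="string"
        )
        jag = _j.jag_probabilities(temp_state, freq_state)

        windows = _t.find_holding_windows(
            cycles, cfg.hold_targets, cfg.holding_tolerance, cfg.min_window_cycles
        )
        steady = _t.steady_state_means(cycles, windows) if windows else None

        q10 = q10_ep = None
        if steady is not None and len(steady) >= 2:
            q10 = _t.fit_q10(steady["mean_temp"], steady["mean_freq"], cfg.T_ref)
            lo, hi = steady.index.min(), steady.index.max()
            q10_ep = _t.endpoint_q10(
                steady.loc[lo, "mean_freq"], steady.loc[lo, "mean_temp"],
                steady.loc[hi, "mean_freq"], steady.loc[hi, "mean_temp"],
            )

        slopes: dict[str, _p.SlopeFit] = {}
        if steady is not None and len(steady) >= 2:
            for ev in _b.PHASE_EVENTS:
                col = steady[f"mean_{ev}"]
                if col.notna().sum() >= 2:
                    slopes[ev] = _p.fit_phase_slope(
                        steady["mean_temp"], col, PHASE_LABELS[ev]
                    )

        return ThermalResponseResults(
            model=self,
            cycles=cycles,
            cycle_table=table,
            assignment=assignment,
            windows=windows,
            steady_state=steady,
            q10=q10,
            q10_endpoint=q10_ep,
            jag=jag,
            phase_slopes=slopes,
        )


@dataclass
class ThermalResponseResults:
    """Fitted single-experiment temperature response."""

    model: ThermalResponseModel
    cycles: list
    cycle_table: pd.DataFrame
    assignment: _b.AssignmentReport
    windows: list
    steady_state: pd.DataFrame | None
    q10: _t.Q10Fit | None
    q10_endpoint: float | None
    jag: _j.JagStats
    phase_slopes: dict = field(default_factory=dict)

    @property
    def condition(self) -> str:
        return self.model.experiment.condition

    def frequency_change(self) -> float | None:
        """Mean-frequency change from the lowest to the highest target °C."""
        if self.steady_state is None or len(self.steady_state) < 2:
            return None
        s = self.steady_state
        return float(s.loc[s.index.max(), "mean_freq"] - s.loc[s.index.min(), "mean_freq"])

    def write_cycle_table(self, path: str | Path) -> None:
        write_cycle_table(self.cycle_table, path)

    def to_dict(self) -> dict:
        d: dict = {
            "condition": self.condition,
            "n_cycles": int(len(self.cycle_table)),
            "jag": {
                "p_dec_given_inc": self.jag.p_dec_given_inc,
                "p_inc_given_stable": self.jag.p_inc_given_stable,
                "n_inc": self.jag.n_inc,
                "n_stable": self.jag.n_stable,
                "n_dec_in_inc": self.jag.n_dec_in_inc,
                "n_inc_in_stable": self.jag.n_inc_in_stable,
            },
            "frequency_change": self.frequency_change(),
            "holding_windows": [
                {
                    "target_temp": w.target_temp,
                    "mean_temp": w.mean_temp,
                    "n_cycles": w.n_cycles,
                    "start_index": w.start_index,
                    "stop_index": w.stop_index,
                }
                for w in self.windows
            ],
        }
        if self.q10 is not None:
            d["q10"] = {
                "Q10": self.q10.Q10,
                "f_ref": self.q10.f_ref,
                "T_ref": self.q10.T_ref,
                "residual_sd": self.q10.residual_sd,
                "n_points": self.q10.n_points,
                "log_slope_se": self.q10.log_slope_se,
                "Q10_endpoint": self.q10_endpoint,
            }
        if self.steady_state is not None:
            d["steady_state"] = {
                f"{idx:g}": {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                }
                for idx, row in self.steady_state.iterrows()
            }
        d["phase_slopes"] = {
            ev: {
                "slope_per_C": s.slope_per_C,
                "slope_per_10C": s.slope_per_10C,
                "intercept": s.intercept,
                "n_temps": s.n_temps,
                "slope_se": s.slope_se,
            }
            for ev, s in self.phase_slopes.items()
        }
        return d

    def summary(self) -> str:
        """Human-readable summary table of the fitted experiment."""
        lines = []
        w = lines.append
        w("Pyloric thermal response")
        w("=" * 60)
        w(f"condition: {self.condition}    cycles: {len(self.cycle_table)}")
        if self.q10 is not None:
            q = self.q10
            w(
                f"Q10 = {q.Q10:.3f} (log-slope SE {q.log_slope_se:.3g}), "
                f"f_ref = {q.f_ref:.3f} Hz at {q.T_ref:g} °C "
                f"[endpoint Q10 {self.q10_endpoint:.3f}]"
            )
        fc = self.frequency_change()
        if fc is not None:
            w(f"frequency change (top - bottom target): {fc:.3f} Hz")
        jag = self.jag
        if jag.p_dec_given_inc is not None:
            w(
                f"P(freq dec | temp inc) = {jag.p_dec_given_inc:.3f} "
                f"({jag.n_dec_in_inc}/{jag.n_inc})"
            )
        if jag.p_inc_given_stable is not None:
            w(
                f"P(freq inc | temp stable) = {jag.p_inc_given_stable:.3f} "
                f"({jag.n_inc_in_stable}/{jag.n_stable})"
            )
        if self.phase_slopes:
            w("-" * 60)
            w("phase vs temperature slopes (per 10 °C; negative = advance)")
            for ev, s in self.phase_slopes.items():
                w(
                    f"  {PHASE_LABELS[ev]:>7}: {s.slope_per_10C:+.4f} "
                    f"(SE {10 * s.slope_se:.4f}, n_temps={s.n_temps})"
                )
        return "\n".join(lines)

    # -- quick-look plots ----------------------------------------------------
    def plot_frequency(self, ax=None):
        """Per-cycle frequency and temperature against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.cycle_table["start_s"]
        ax.plot(t, self.cycle_table["freq_hz"], lw=0.6, color="tab:blue")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)", color="tab:blue")
        ax2 = ax.twinx()
        ax2.plot(t, self.cycle_table["temp_c"], lw=0.8, color="tab:red")
        ax2.set_ylabel("temperature (°C)", color="tab:red")
        return ax

    def plot_phases(self, ax=None):
        """Mean phase of each event at each holding temperature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.steady_state is None:
            raise ValueError("no holding windows; nothing to plot")
        for ev in _b.PHASE_EVENTS:
            col = self.steady_state[f"mean_{ev}"]
            ax.plot(self.steady_state["mean_temp"], col, "o-",
                    label=PHASE_LABELS[ev])
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("phase (fraction of period)")
        ax.legend(fontsize=8)
        return ax
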