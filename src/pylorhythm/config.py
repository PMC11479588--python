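"""Run configuration shared by every analysis stage.

All thresholds live here so that a whole analysis is reproducible from a
single JSON file.  Time is seconds and temperature is degrees Celsius
throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass
class RunConfig:
    """Parameters of a full pyloric-rhythm temperature analysis.

    Parameters
    ----------
    burst_min_spikes : int
        Minimum spikes for a group to count as a burst (default 2).
    burst_min_gap : float
        Inter-burst interval in seconds; a gap of at least this long splits
        bursts (default 0.200 s).
    holding_tolerance : float
        Half-width in °C of the band around a target temperature that counts
        as "holding" (default 0.3 °C).
    freq_smooth_window : int
        Moving-average window in cycles for the frequency series (default 30).
    temp_smooth_window : int
        Moving-average window in cycles for the temperature series (default 10).
    temp_increase_threshold : float
        Per-cycle smoothed-temperature change above which a cycle is labelled
        temperature-increasing (default 0.01 °C/cycle, strict inequality).
    freq_change_threshold : float
        Per-cycle smoothed-frequency change beyond which a cycle is labelled
        frequency increasing/decreasing (default 0.002 Hz/cycle, strict).
    T_ref : float
        Reference temperature for Q10 fits (default 11 °C).
    hold_targets : sequence of float
        Protocol holding temperatures (default 11..21 °C in 2 °C steps).
    min_window_cycles : int
        Shortest run of in-band cycles kept as a holding window (default 10).
    period_match_tolerance : float
        Maximum |Δperiod| in seconds for period-matched cycle pairing
        (default 0.02 s).
    alpha : float
        Significance level for normality gates and tests (default 0.05).
    n_phase_tests : int
        Bonferroni multiplier for the phase-slope battery
        (default 10 = 5 phases x 2 conditions).
    rng_seed : int
        Seed for any stochastic step (default 0).
    """

    burst_min_spikes: int = 2
    burst_min_gap: float = 0.200
    holding_tolerance: float = 0.3
    freq_smooth_window: int = 30
    temp_smooth_window: int = 10
    temp_increase_threshold: float = 0.01
    freq_change_threshold: float = 0.002
    T_ref: float = 11.0
    hold_targets: Sequence[float] = field(
        default_factory=lambda: (11.0, 13.0, 15.0, 17.0, 19.0, 21.0)
    )
    min_window_cycles: int = 10
    period_match_tolerance: float = 0.02
    alpha: float = 0.05
    n_phase_tests: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "burst_min_gap",
            "holding_tolerance",
            "temp_increase_threshold",
            "freq_change_threshold",
            "period_match_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("burst_min_spikes", "freq_smooth_window",
                     "temp_smooth_window", "min_window_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.hold_targets = tuple(float(t) for t in self.hold_targets)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
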