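"""Burst detection, pyloric cycles, phases and period matching.

A burst is a maximal run of spikes whose internal gaps are all shorter than
the inter-burst interval (default 200 ms); runs with fewer than the minimum
spike count are discarded outright.  Cycles run from the first spike of one
PD burst to the first spike of the next, and every phase is the event time
relative to the cycle start divided by the period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import SpikeTrain

FOLLOWER_EVENTS = ("lp_on", "lp_off", "py_on", "py_off")
PHASE_EVENTS = ("pd_off",) + FOLLOWER_EVENTS


@dataclass(frozen=True)
class Burst:
    unit_label: str
    onset: float
    offset: float
    n_spikes: int
    spikes: np.ndarray = field(repr=False)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Cycle:
    """One pyloric cycle: [start, end) between consecutive PD burst onsets."""

    index: int
    start: float
    end: float
    events: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float | None = None

    @property
    def period(self) -> float:
        return self.end - self.start

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


@dataclass(frozen=True)
class PhaseSet:
    """Burst onset/offset times of one cycle normalised by its period."""

    pd_off: float | None = None
    lp_on: float | None = None
    lp_off: float | None = None
    py_on: float | None = None
    py_off: float | None = None
    pd_duration: float | None = None
    lp_duty: float | None = None
    delay_lp_on_minus_pd_off: float | None = None
    spilled: frozenset = frozenset()


@dataclass
class AssignmentReport:
    """Book-keeping of follower-burst -> cycle assignment."""

    dropped_extras: dict[str, int] = field(default_factory=dict)
    outside: dict[str, int] = field(default_factory=dict)


def detect_bursts(train: SpikeTrain, min_spikes: int = 2, min_gap: float = 0.200) -> list[Burst]:
    """Partition a spike train into bursts.

    A gap of ``min_gap`` or more ("an inter-burst interval of at least
    200 ms") splits the train; groups with fewer than ``min_spikes`` spikes
    are discarded, not merged into neighbours.
    """
    if min_spikes < 1:
        raise ValueError("min_spikes must be >= 1")
    if min_gap <= 0:
        raise ValueError("min_gap must be > 0")
    t = np.asarray(train.times, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("spike train must be strictly ascending")
    if t.size == 0:
        return []
    # split where the gap reaches min_gap; internal gaps are all < min_gap
    cut = np.flatnonzero(np.diff(t) >= min_gap) + 1
    groups = np.split(t, cut)
    return [
        Burst(train.unit_label, g[0], g[-1], int(g.size), g)
        for g in groups
        if g.size >= min_spikes
    ]


def build_cycles(pd_bursts: Sequence[Burst]) -> list[Cycle]:
    """Cycles between consecutive PD burst onsets.

    Each cycle carries its defining PD burst's (onset, offset) in
    ``events['PD']``.
    """
    if len(pd_bursts) < 2:
        raise ValueError("insufficient bursts: need >= 2 PD bursts to form a cycle")
    onsets = np.array([b.onset for b in pd_bursts])
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("PD bursts must be ordered with ascending onsets")
    return [
        Cycle(i, b.onset, nxt.onset, events={"PD": (b.onset, b.offset)})
        for i, (b, nxt) in enumerate(zip(pd_bursts[:-1], pd_bursts[1:]))
    ]


def assign_events(
    cycles: Sequence[Cycle],
    follower_bursts: Mapping[str, Sequence[Burst]],
) -> AssignmentReport:
    """Assign follower (LP/PY) bursts to the cycle containing their onset.

    If several bursts of one unit start inside one cycle the first is kept
    and the extras are counted; bursts starting before the first or after the
    last cycle are counted as outside.  The burst offset may spill past the
    cycle end.  Mutates ``cycles`` in place and returns the counters.
    """
    report = AssignmentReport()
    starts = np.array([c.start for c in cycles])
    end = cycles[-1].end
    for unit, bursts in follower_bursts.items():
        dropped = outside = 0
        for b in bursts:
            if b.onset < starts[0] or b.onset >= end:
                outside += 1
                continue
            i = int(np.searchsorted(starts, b.onset, side="right")) - 1
            if unit in cycles[i].events:
                dropped += 1
                continue
            cycles[i].events[unit] = (b.onset, b.offset)
        report.dropped_extras[unit] = dropped
        report.outside[unit] = outside
    return report


def compute_phases(cycle: Cycle) -> PhaseSet:
    """Normalise a cycle's event times by its period.

    phase(event) = (event_time - start) / period.  Absent units yield absent
    fields; offsets past the cycle end give phases > 1 and are flagged in
    ``spilled``.
    """
    if "PD" not in cycle.events:
        raise ValueError("cycle has no PD events")
    if cycle.period <= 0:
        raise ValueError("cycle period must be > 0")
    start, period = cycle.start, cycle.period
    ph = lambda t: (t - start) / period

    pd_on, pd_off_t = cycle.events["PD"]
    out: dict[str, float | None] = {
        "pd_off": ph(pd_off_t),
        "pd_duration": pd_off_t - pd_on,
    }
    spilled = set()
    for unit in ("LP", "PY"):
        key = unit.lower()
        if unit in cycle.events:
            on_t, off_t = cycle.events[unit]
            out[f"{key}_on"] = ph(on_t)
            out[f"{key}_off"] = ph(off_t)
            if ph(off_t) > 1.0:
                spilled.add(unit)
        else:
            out[f"{key}_on"] = out[f"{key}_off"] = None
    if out["lp_on"] is not None:
        out["lp_duty"] = out["lp_off"] - out["lp_on"]
        out["delay_lp_on_minus_pd_off"] = out["lp_on"] - out["pd_off"]
    else:
        out["lp_duty"] = out["delay_lp_on_minus_pd_off"] = None
    return PhaseSet(spilled=frozenset(spilled), **out)


@dataclass(frozen=True)
class MatchedPair:
    a_index: int
    b_index: int
    period_a: float
    period_b: float
    #: latency differences (a minus b) in ms; positive = event earlier in b
    lp_on_diff_ms: float | None = None
    pd_off_diff_ms: float | None = None
    py_on_diff_ms: float | None = None


def _latency_ms(cycle: Cycle, unit: str, which: int) -> float | None:
    if unit not in cycle.events:
        return None
    return (cycle.events[unit][which] - cycle.start) * 1e3


def match_periods(
    cycles_a: Sequence[Cycle],
    cycles_b: Sequence[Cycle],
    tolerance: float,
) -> list[MatchedPair]:
    """One-to-one pairing of cycles with near-equal periods.

    Finds an optimal assignment that first maximises the number of pairs with
    |period_a - period_b| <= tolerance and then minimises the total period
    discrepancy.  Returns the pairs with per-pair latency differences (in ms,
    a minus b) for LP onset, PD offset and PY onset.
    """
    import warnings

    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not cycles_a or not cycles_b:
        warnings.warn("match_periods: empty cycle sequence, no pairs", stacklevel=2)
        return []
    pa = np.array([c.period for c in cycles_a])
    pb = np.array([c.period for c in cycles_b])
    cost = np.abs(pa[:, None] - pb[None, :])
    big = 1e6  # dominates any feasible total so infeasible pairs are last resort
    cost = np.where(cost <= tolerance, cost, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for i, j in zip(rows, cols):
        if cost[i, j] >= big:
            continue
        ca, cb = cycles_a[i], cycles_b[j]
        diff = lambda u, w: (
            None
            if _latency_ms(ca, u, w) is None or _latency_ms(cb, u, w) is None
            else _latency_ms(ca, u, w) - _latency_ms(cb, u, w)
        )
        pairs.append(
            MatchedPair(
                ca.index, cb.index, ca.period, cb.period,
                lp_on_diff_ms=diff("LP", 0),
                pd_off_diff_ms=diff("PD", 1),
                py_on_diff_ms=diff("PY", 0),
            )
        )
    if not pairs:
        warnings.warn("match_periods: no period-matched pairs found", stacklevel=2)
    return pairs
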