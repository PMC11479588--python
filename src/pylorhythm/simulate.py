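"""Ground-truth synthetic experiments: temperature protocols, spike trains
and voltage-clamp traces.

The generator states the experimental world the analysis assumes: a step
protocol from 11 to 21 °C in 2 °C steps with ~4 min per step, steady-state
frequency following f(T) = f_ref * Q10**((T - T_ref)/10), an optional
first-order adaptation state that transiently depresses frequency while
temperature ramps (the "jag", relaxing with a ~30 s time constant once the
ramp ends), per-unit burst phases with optional linear temperature drift,
and Gaussian spike-timing jitter.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clamp import ClampTrace
from .io import ExperimentRecord, SpikeTrain, TemperatureTrace


@dataclass
class Protocol:
    """Temperature step protocol (11→21 °C, 2 °C steps, 4 min per step)."""

    start_temp: float = 11.0
    step_size: float = 2.0
    n_steps: int = 5
    ramp_duration: float = 40.0
    hold_duration: float = 200.0  # ramp + hold = 240 s per step
    initial_hold_duration: float = 120.0
    return_to_start: bool = False
    sample_interval: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ramp_duration", "hold_duration", "initial_hold_duration",
                     "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    @property
    def targets(self) -> tuple[float, ...]:
        return tuple(self.start_temp + self.step_size * i
                     for i in range(self.n_steps + 1))

    def template(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear (time, temperature) node points, noise-free."""
        t, v = [0.0], [self.start_temp]
        now, temp = self.initial_hold_duration, self.start_temp
        t.append(now)
        v.append(temp)
        for _ in range(self.n_steps):
            temp += self.step_size
            now += self.ramp_duration
            t.append(now)
            v.append(temp)
            now += self.hold_duration
            t.append(now)
            v.append(temp)
        if self.return_to_start:
            now += self.ramp_duration * max(self.n_steps, 1)
            t.append(now)
            v.append(self.start_temp)
            now += self.hold_duration
            t.append(now)
            v.append(self.start_temp)
        return np.asarray(t), np.asarray(v)


@dataclass
class GroundTruth:
    """Full generative parameter set of one synthetic experiment.

    Phases are fractions of the period at ``T_ref``; ``phase_slopes`` add a
    linear drift per °C.  ``jag_gain`` (Hz per °C/s of ramp rate) scales the
    transient frequency depression while temperature rises; the adaptation
    state relaxes with time constant ``jag_tau``.
    """

    condition: str = "saline"
    f_ref: float = 1.2
    Q10: float = 1.7
    T_ref: float = 11.0
    jag_gain: float = 0.5
    jag_tau: float = 30.0
    phases: dict = field(default_factory=lambda: {
        "pd_off": 0.19, "lp_on": 0.40, "lp_off": 0.66,
        "py_on": 0.58, "py_off": 0.87,
    })
    phase_slopes: dict = field(default_factory=lambda: {
        "pd_off": 0.0, "lp_on": 0.0, "lp_off": -0.007,
        "py_on": 0.0, "py_off": 0.0,
    })
    spikes_per_burst: dict = field(default_factory=lambda: {
        "PD": 5, "LP": 8, "PY": 6,
    })
    spike_jitter_sd: float = 0.005
    pd_burst_duration: float | None = None  # seconds; overrides pd_off phase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_ref <= 0 or self.Q10 <= 0 or self.jag_tau <= 0:
            raise ValueError("f_ref, Q10 and jag_tau must be > 0")

    @classmethod
    def saline(cls, seed: int = 0, **kw) -> "GroundTruth":
        """Control-like parameters (Q10 1.7, 1.2 Hz at 11 °C, small jag)."""
        return cls(condition="saline", seed=seed, **kw)

    @classmethod
    def cesium(cls, seed: int = 0, **kw) -> "GroundTruth":
        """Cs-like parameters: lower f_ref and Q10, advanced PD/LP phases,
        stronger LP drift and a pronounced jag."""
        defaults = dict(
            condition="Cs", f_ref=0.9, Q10=1.3, jag_gain=3.0,
            phases={"pd_off": 0.12, "lp_on": 0.29, "lp_off": 0.56,
                    "py_on": 0.60, "py_off": 0.90},
            phase_slopes={"pd_off": 0.0, "lp_on": -0.005, "lp_off": -0.014,
                          "py_on": 0.0, "py_off": 0.0},
        )
        defaults.update(kw)
        return cls(seed=seed, **defaults)

    @classmethod
    def cesium_ptx(cls, seed: int = 0, **kw) -> "GroundTruth":
        """Cs+PTX-like: control-level temperature sensitivity but jags persist."""
        defaults = dict(condition="Cs+PTX", f_ref=0.9, Q10=1.7, jag_gain=3.0)
        defaults.update(kw)
        return cls(seed=seed, **defaults)

    def phases_at(self, T: float) -> dict[str, float]:
        return {k: self.phases[k] + self.phase_slopes.get(k, 0.0) * (T - self.T_ref)
                for k in self.phases}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_protocol(p: Protocol, seed: int | None = None) -> TemperatureTrace:
    """Sample the protocol's piecewise-linear temperature template.

    Optional Normal(0, ``p.noise_sd``) measurement noise; deterministic
    given the seed.
    """
    nodes_t, nodes_v = p.template()
    t = np.arange(0.0, nodes_t[-1] + p.sample_interval / 2, p.sample_interval)
    v = np.interp(t, nodes_t, nodes_v)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed if seed is None else seed)
        v = v + rng.normal(0.0, p.noise_sd, v.size)
    return TemperatureTrace(t, v)


def _frequency_trajectory(
    gt: GroundTruth, trace: TemperatureTrace, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (t, T, f) with the first-order jag adaptation state.

    x tracks the (non-negative) warming rate with time constant jag_tau:
    dx/dt = (max(dT/dt, 0) - x)/jag_tau, stepped exactly for piecewise-
    constant rate; f = f_ss(T) - jag_gain * x, floored at a small positive
    frequency.
    """
    t = np.arange(trace.times[0], trace.times[-1] + dt / 2, dt)
    T = np.interp(t, trace.times, trace.values)
    rate = np.maximum(np.gradient(T, dt), 0.0)
    a = np.exp(-dt / gt.jag_tau)
    x = np.empty_like(t)
    x[0] = 0.0
    for i in range(1, t.size):
        x[i] = x[i - 1] * a + rate[i - 1] * (1.0 - a)
    f_ss = gt.f_ref * gt.Q10 ** ((T - gt.T_ref) / 10.0)
    f = np.maximum(f_ss - gt.jag_gain * x, 0.05)
    return t, T, f


def simulate_experiment(
    gt: GroundTruth,
    p: Protocol | None = None,
    *,
    dt: float = 0.01,
) -> tuple[ExperimentRecord, GroundTruth]:
    """Generate one synthetic experiment (PD, LP, PY trains + temperature).

    Cycle boundaries are the crossings of the integrated instantaneous
    frequency through successive integers; within each complete cycle the
    units burst at their (temperature-drifted) phase parameters, with
    ``spikes_per_burst`` evenly spaced spikes per burst and independent
    Gaussian timing jitter.  RNG draw order: PD, LP, PY jitter (one stream
    seeded by ``gt.seed``).
    """
    if p is None:
        p = Protocol()
    trace = make_protocol(p, seed=gt.seed + 1 if p.noise_sd > 0 else None)

    lo, hi = trace.values.min(), trace.values.max()
    for T in (lo, hi):
        ph = gt.phases_at(T)
        order = [ph["pd_off"], ph["lp_on"], ph["lp_off"]]
        if not (0 < order[0] < order[1] < order[2]) or not (0 < ph["py_on"] < ph["py_off"]):
            raise ValueError(f"phase ordering violated after drift at {T:.2f} °C: {ph}")

    t, T, f = _frequency_trajectory(gt, trace, dt)
    phi = np.concatenate([[0.0], np.cumsum((f[:-1] + f[1:]) / 2.0 * dt)])
    n_cycles = int(np.floor(phi[-1]))
    if n_cycles < 2:
        raise ValueError("protocol too short: fewer than 2 complete cycles")
    starts = np.interp(np.arange(n_cycles + 1, dtype=float), phi, t)
    periods = np.diff(starts)
    T_start = np.interp(starts, t, T)

    rng = np.random.default_rng(gt.seed)
    slopes = {k: gt.phase_slopes.get(k, 0.0) for k in gt.phases}

    def phase_arr(key: str) -> np.ndarray:
        return gt.phases[key] + slopes[key] * (T_start[:-1] - gt.T_ref)

    def burst_matrix(on_t: np.ndarray, off_t: np.ndarray, n_sp: int) -> np.ndarray:
        frac = np.linspace(0.0, 1.0, n_sp)
        return on_t[:, None] + (off_t - on_t)[:, None] * frac[None, :]

    trains: dict[str, SpikeTrain] = {}
    cycle_start = starts[:-1]

    # PD: burst begins at the cycle start
    pd_on = cycle_start
    if gt.pd_burst_duration is not None:
        pd_off = cycle_start + gt.pd_burst_duration
    else:
        pd_off = cycle_start + phase_arr("pd_off") * periods
    # one extra PD burst at the final boundary so the last cycle is closed
    last_dur = pd_off[-1] - pd_on[-1]
    pd_on_all = np.concatenate([pd_on, [starts[-1]]])
    pd_off_all = np.concatenate([pd_off, [starts[-1] + last_dur]])

    unit_events = {
        "PD": (pd_on_all, pd_off_all),
        "LP": (cycle_start + phase_arr("lp_on") * periods,
               cycle_start + phase_arr("lp_off") * periods),
        "PY": (cycle_start + phase_arr("py_on") * periods,
               cycle_start + phase_arr("py_off") * periods),
    }
    for unit in ("PD", "LP", "PY"):  # documented draw order
        on_t, off_t = unit_events[unit]
        n_sp = int(gt.spikes_per_burst[unit])
        spikes = burst_matrix(on_t, off_t, n_sp)
        if gt.spike_jitter_sd > 0:
            spikes = spikes + rng.normal(0.0, gt.spike_jitter_sd, spikes.shape)
        flat = np.unique(np.sort(spikes.ravel()))
        flat = flat[flat >= 0]
        trains[unit] = SpikeTrain(unit, flat)

    record = ExperimentRecord(
        condition=gt.condition,
        trains=trains,
        temperature=trace,
        metadata={
            "generator": "pylorhythm.simulate.simulate_experiment",
            "seed": gt.seed,
            "n_cycles": n_cycles,
            "protocol_targets": list(p.targets),
        },
    )
    return record, gt


def simulate_clamp_trace(
    I_hold: float = -2.0,
    ih_amplitude: float = 1.5,
    tau: float = 2.0,
    duration: float = 12.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    sample_rate: float = 1000.0,
    baseline: float = 0.5,
    I_pre: float = 0.0,
) -> ClampTrace:
    """Idealised voltage-clamp current during a long hyperpolarizing step.

    During the step the holding current relaxes from ``I_hold`` by
    ``ih_amplitude`` with an exponential time constant ``tau`` (I_h
    activation makes the inward holding current grow):
    I(t) = I_hold - ih_amplitude * (1 - exp(-t/tau)).
    """
    if duration <= 0 or tau <= 0:
        raise ValueError("duration and tau must be > 0")
    dt = 1.0 / sample_rate
    t = np.arange(0.0, baseline + duration + dt / 2, dt)
    i = np.full_like(t, I_pre)
    in_step = t >= baseline
    ts = t[in_step] - baseline
    i[in_step] = I_hold - ih_amplitude * (1.0 - np.exp(-ts / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, i.size)
    return ClampTrace(t, i, step_onset=baseline, step_duration=duration)
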