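import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pylorhythm.bursts import (Burst, Cycle, assign_events, build_cycles,
                               compute_phases, detect_bursts, match_periods)
from pylorhythm.io import SpikeTrain


def brute_force_bursts(times, min_spikes, min_gap):
    """Oracle: group spikes by scanning every split point."""
    groups, current = [], []
    for t in times:
        if current and t - current[-1] >= min_gap:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return [g for g in groups if len(g) >= min_spikes]


class TestDetectBursts:
    def test_basic_grouping(self):
        train = SpikeTrain("PD", [0.00, 0.05, 0.10, 0.50, 0.55, 1.00])
        bursts = detect_bursts(train, min_spikes=2, min_gap=0.2)
        assert [(b.onset, b.offset, b.n_spikes) for b in bursts] == [
            (0.00, 0.10, 3), (0.50, 0.55, 2),
        ]

    def test_boundary_gap_splits(self):
        # a gap of exactly the inter-burst interval separates bursts
        bursts = detect_bursts(SpikeTrain("PD", [0.0, 0.2]), min_spikes=2, min_gap=0.2)
        assert bursts == []

    def test_empty_train(self):
        assert detect_bursts(SpikeTrain("PD", [])) == []

    def test_unsorted_errors(self):
        train = SpikeTrain("PD", [0.0, 1.0])
        object.__setattr__(train, "times", np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="ascending"):
            detect_bursts(train)

    def test_equivalence_with_brute_force_oracle(self, rng):
        """1000 random trains must partition exactly as the scanning oracle."""
        for _ in range(1000):
            n = rng.integers(0, 40)
            times = np.unique(np.round(rng.uniform(0, 5, n), 4))
            min_spikes = int(rng.integers(1, 4))
            min_gap = float(rng.uniform(0.05, 0.5))
            got = detect_bursts(SpikeTrain("PD", times), min_spikes, min_gap)
            exp = brute_force_bursts(times.tolist(), min_spikes, min_gap)
            assert len(got) == len(exp)
            for b, g in zip(got, exp):
                assert np.allclose(b.spikes, g)

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_idempotent_partition(self, raw):
        times = np.unique(np.asarray(raw))
        bursts = detect_bursts(SpikeTrain("PD", times), 2, 0.2)
        kept = np.concatenate([b.spikes for b in bursts]) if bursts else np.array([])
        again = detect_bursts(SpikeTrain("PD", kept), 2, 0.2)
        assert len(again) == len(bursts)
        for a, b in zip(again, bursts):
            assert np.array_equal(a.spikes, b.spikes)


def _bursts_from_onsets(onsets, duration=0.1, unit="PD"):
    return [Burst(unit, o, o + duration, 2, np.array([o, o + duration]))
            for o in onsets]


class TestBuildCycles:
    def test_periods_and_frequencies(self):
        cycles = build_cycles(_bursts_from_onsets([0.0, 1.0, 2.1]))
        assert np.allclose([c.period for c in cycles], [1.0, 1.1])
        assert np.allclose([c.frequency for c in cycles], [1.0, 1 / 1.1])

    def test_two_bursts_one_cycle(self):
        assert len(build_cycles(_bursts_from_onsets([0.0, 1.0]))) == 1

    def test_insufficient_bursts(self):
        with pytest.raises(ValueError, match="insufficient"):
            build_cycles(_bursts_from_onsets([0.0]))

    def test_fixed_oscillator_frequencies(self):
        onsets = np.arange(100) / 1.25
        cycles = build_cycles(_bursts_from_onsets(list(onsets)))
        assert np.allclose([c.frequency for c in cycles], 1.25)

    def test_period_conservation(self, rng):
        onsets = np.sort(rng.uniform(0, 100, 50))
        cycles = build_cycles(_bursts_from_onsets(list(onsets)))
        assert np.isclose(sum(c.period for c in cycles), onsets[-1] - onsets[0])


class TestAssignEvents:
    def test_onset_containment(self):
        cycles = build_cycles(_bursts_from_onsets([0.0, 1.0]))
        rep = assign_events(cycles, {"LP": _bursts_from_onsets([0.40], unit="LP")})
        assert cycles[0].events["LP"] == (0.40, 0.50)
        assert rep.dropped_extras["LP"] == 0

    def test_first_burst_wins(self):
        cycles = build_cycles(_bursts_from_onsets([0.0, 1.0]))
        rep = assign_events(cycles, {"LP": _bursts_from_onsets([0.3, 0.7], unit="LP")})
        assert cycles[0].events["LP"][0] == 0.3
        assert rep.dropped_extras["LP"] == 1

    def test_offset_spill_flagged(self):
        cycles = build_cycles(_bursts_from_onsets([0.0, 1.0]))
        lp = [Burst("LP", 0.99, 1.10, 2, np.array([0.99, 1.10]))]
        assign_events(cycles, {"LP": lp})
        phases = compute_phases(cycles[0])
        assert phases.lp_off > 1.0
        assert "LP" in phases.spilled

    def test_outside_counted_not_error(self):
        cycles = build_cycles(_bursts_from_onsets([1.0, 2.0]))
        rep = assign_events(cycles, {"LP": _bursts_from_onsets([0.1, 5.0], unit="LP")})
        assert rep.outside["LP"] == 2


class TestComputePhases:
    def test_printed_mean_construction(self):
        # constructed at the printed saline means: PD OFF 0.19, LP ON 0.40,
        # LP OFF 0.66, delay LP ON - PD OFF = 0.21
        cyc = Cycle(0, 0.0, 1.0, events={"PD": (0.0, 0.19), "LP": (0.40, 0.66)})
        p = compute_phases(cyc)
        assert np.isclose(p.pd_off, 0.19)
        assert np.isclose(p.lp_on, 0.40)
        assert np.isclose(p.lp_off, 0.66)
        assert np.isclose(p.delay_lp_on_minus_pd_off, 0.21)
        assert np.isclose(p.lp_duty, 0.26)

    def test_translation_and_scale(self):
        cyc = Cycle(0, 5.0, 7.0, events={"PD": (5.0, 5.4), "LP": (5.8, 6.2)})
        p = compute_phases(cyc)
        assert np.isclose(p.lp_on, 0.40)

    def test_absent_py_fields(self):
        cyc = Cycle(0, 0.0, 1.0, events={"PD": (0.0, 0.19)})
        p = compute_phases(cyc)
        assert p.py_on is None and p.py_off is None and p.lp_duty is None

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_phase_invariance_under_affine_time(self, shift, scale):
        ev = {"PD": (0.0, 0.2), "LP": (0.4, 0.7), "PY": (0.6, 0.9)}
        base = compute_phases(Cycle(0, 0.0, 1.0, events=dict(ev)))
        moved = {
            u: (a * scale + shift, b * scale + shift) for u, (a, b) in ev.items()
        }
        other = compute_phases(Cycle(0, shift, scale + shift, events=moved))
        for name in ("pd_off", "lp_on", "lp_off", "py_on", "py_off"):
            assert np.isclose(getattr(base, name), getattr(other, name), atol=1e-9)


def brute_force_match(pa, pb, tol):
    """Oracle: exhaustive one-to-one pairing maximising pair count, then
    minimising total |Δperiod|."""
    best = (0, 0.0, [])
    na, nb = len(pa), len(pb)
    for k in range(min(na, nb), -1, -1):
        found = None
        for aidx in itertools.combinations(range(na), k):
            for bperm in itertools.permutations(range(nb), k):
                if all(abs(pa[i] - pb[j]) <= tol for i, j in zip(aidx, bperm)):
                    cost = sum(abs(pa[i] - pb[j]) for i, j in zip(aidx, bperm))
                    if found is None or cost < found[0]:
                        found = (cost, list(zip(aidx, bperm)))
        if found:
            return k, found[0], found[1]
    return 0, 0.0, []


class TestMatchPeriods:
    def _cycles(self, periods):
        start = 0.0
        out = []
        for i, p in enumerate(periods):
            out.append(Cycle(i, start, start + p, events={"PD": (start, start + 0.1)}))
            start += p
        return out

    def test_single_nearest_pair(self):
        pairs = match_periods(self._cycles([1.00]), self._cycles([1.01, 1.30]), 0.02)
        assert len(pairs) == 1
        assert (pairs[0].period_a, pairs[0].period_b) == (1.00, 1.01)

    def test_identical_sequences_zero_latency(self):
        a = self._cycles([1.0, 1.1, 0.9])
        pairs = match_periods(a, self._cycles([1.0, 1.1, 0.9]), 0.001)
        assert len(pairs) == 3
        assert all(p.pd_off_diff_ms == 0.0 for p in pairs)

    def test_no_pairs_warns(self):
        with pytest.warns(UserWarning, match="no period-matched"):
            assert match_periods(self._cycles([1.0]), self._cycles([2.0]), 0.01) == []

    def test_against_exhaustive_oracle(self, rng):
        for _ in range(60):
            na, nb = rng.integers(1, 7), rng.integers(1, 7)
            pa = np.round(rng.uniform(0.5, 1.5, na), 3)
            pb = np.round(rng.uniform(0.5, 1.5, nb), 3)
            tol = 0.05
            pairs = match_periods(self._cycles(pa), self._cycles(pb), tol)
            k, cost, _ = brute_force_match(list(pa), list(pb), tol)
            assert len(pairs) == k
            got_cost = sum(abs(p.period_a - p.period_b) for p in pairs)
            assert got_cost <= cost + 1e-9
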