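import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pylorhythm.bursts import Cycle
from pylorhythm.io import TemperatureTrace
from pylorhythm.thermal import (annotate_temperature, condition_difference,
                                endpoint_q10, find_holding_windows, fit_q10,
                                steady_state_means)


def _cycles(starts_ends, temps=None):
    out = [Cycle(i, s, e, events={"PD": (s, s + 0.1)}) for i, (s, e) in enumerate(starts_ends)]
    if temps is not None:
        for c, t in zip(out, temps):
            c.temperature = t
    return out


class TestAnnotateTemperature:
    def test_constant_trace(self):
        trace = TemperatureTrace([0.0, 100.0], [11.0, 11.0])
        cycles = _cycles([(0, 1), (1, 2.2), (50, 51)])
        annotate_temperature(cycles, trace)
        assert all(np.isclose(c.temperature, 11.0) for c in cycles)

    def test_linear_ramp_midpoint(self):
        trace = TemperatureTrace([0.0, 10.0], [11.0, 13.0])
        cycles = _cycles([(0, 10)])
        annotate_temperature(cycles, trace)
        assert np.isclose(cycles[0].temperature, 12.0)

    def test_extrapolation_warns(self):
        trace = TemperatureTrace([0.0, 1.0], [11.0, 11.0])
        cycles = _cycles([(0.5, 2.0)])
        with pytest.warns(UserWarning, match="extrapolation"):
            annotate_temperature(cycles, trace)
        assert np.isclose(cycles[0].temperature, 11.0)

    def test_against_quadrature_oracle(self, rng):
        """Cycle means agree with dense numerical quadrature to < 1e-6 °C."""
        t = np.sort(rng.uniform(0, 100, 80))
        t[0], t[-1] = 0.0, 100.0
        t = np.unique(t)
        v = rng.uniform(10, 22, t.size)
        trace = TemperatureTrace(t, v)
        starts = np.sort(rng.uniform(0, 95, 20))
        cycles = _cycles([(s, s + rng.uniform(0.5, 3.0)) for s in starts])
        annotate_temperature(cycles, trace)
        for c in cycles:
            grid = np.linspace(c.start, min(c.end, 100.0), 20001)
            oracle = np.trapezoid(np.interp(grid, t, v), grid) / (grid[-1] - grid[0])
            assert abs(c.temperature - oracle) < 1e-6


class TestFindHoldingWindows:
    def test_two_holds(self):
        temps = [11.0] * 20 + [12.0] * 5 + [13.05] * 20
        cycles = _cycles([(i, i + 1) for i in range(len(temps))], temps)
        wins = find_holding_windows(cycles, [11, 13], 0.3, min_cycles=10)
        assert [(w.target_temp, w.n_cycles) for w in wins] == [(11.0, 20), (13.0, 20)]

    def test_no_windows(self):
        cycles = _cycles([(i, i + 1) for i in range(30)], [12.0] * 30)
        with pytest.warns(UserWarning, match="no holding window"):
            assert find_holding_windows(cycles, [11, 13], 0.3) == []

    def test_short_runs_discarded_and_disjoint(self):
        temps = [11.0] * 12 + [13.0] * 5 + [11.0] * 15
        cycles = _cycles([(i, i + 1) for i in range(len(temps))], temps)
        with pytest.warns(UserWarning):
            wins = find_holding_windows(cycles, [11, 13], 0.3, min_cycles=10)
        assert [(w.target_temp, w.n_cycles) for w in wins] == [(11.0, 12), (11.0, 15)]
        # each cycle belongs to at most one window
        members = [i for w in wins for i in range(w.start_index, w.stop_index)]
        assert len(members) == len(set(members))


class TestSteadyStateMeans:
    def test_arithmetic(self):
        cycles = _cycles([(0, 1.0), (1.0, 1.0 + 1 / 1.2)], [11.0, 11.0])
        wins = find_holding_windows(cycles, [11], 0.3, min_cycles=2)
        tab = steady_state_means(cycles, wins)
        assert np.isclose(tab.loc[11.0, "mean_freq"], 1.1)
        assert np.isclose(tab.loc[11.0, "sd_freq"], np.sqrt(0.02), atol=1e-12)
        assert tab.loc[11.0, "n"] == 2

    def test_single_cycle_window_sd_zero(self):
        cycles = _cycles([(0, 1.0)], [11.0])
        wins = find_holding_windows(cycles, [11], 0.3, min_cycles=1)
        tab = steady_state_means(cycles, wins)
        assert tab.loc[11.0, "sd_freq"] == 0.0


class TestFitQ10:
    def test_exact_model_six_points(self):
        T = np.array([11, 13, 15, 17, 19, 21], dtype=float)
        f = 1.0 * 2.0 ** ((T - 11) / 10)
        fit = fit_q10(T, f, T_ref=11)
        assert np.isclose(fit.Q10, 2.0)
        assert np.isclose(fit.f_ref, 1.0)
        assert fit.residual_sd < 1e-14

    def test_two_points_printed_values(self):
        fit = fit_q10([11, 21], [1.2, 2.1], T_ref=11)
        assert np.isclose(fit.Q10, 1.75)
        assert np.isclose(fit.f_ref, 1.2)
        assert fit.residual_sd == 0.0

    def test_against_ols_oracle(self, rng):
        """Log-space OLS agrees with the closed-form normal equations."""
        for _ in range(50):
            T = np.sort(rng.uniform(10, 25, rng.integers(3, 12)))
            f = np.exp(rng.normal(0.2, 0.4, T.size))
            fit = fit_q10(T, f, T_ref=11)
            x = (T - 11) / 10
            y = np.log(f)
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * x.mean()
            assert abs(np.log(fit.Q10) - slope) < 1e-10
            assert abs(np.log(fit.f_ref) - intercept) < 1e-10

    @given(c=st.floats(0.1, 10, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        T = np.array([11.0, 13, 15, 17])
        f = np.array([1.0, 1.2, 1.5, 1.9])
        base = fit_q10(T, f)
        scaled = fit_q10(T, c * f)
        assert np.isclose(scaled.Q10, base.Q10)
        assert np.isclose(scaled.f_ref, c * base.f_ref)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_q10([11], [1.0])
        with pytest.raises(ValueError):
            fit_q10([11, 21], [1.0, -2.0])

    def test_recovery_under_lognormal_noise(self, rng):
        """Monte-Carlo: mean recovered Q10 within 3 SE of truth."""
        true_q10 = 1.7
        T = np.array([11, 13, 15, 17, 19, 21], dtype=float)
        ests = []
        for _ in range(1000):
            f = 1.2 * true_q10 ** ((T - 11) / 10) * np.exp(rng.normal(0, 0.05, T.size))
            ests.append(fit_q10(T, f).Q10)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - true_q10) < 3 * se + 3 * 0.05 * true_q10 / np.sqrt(1000)


class TestEndpointQ10:
    def test_printed_worked_example(self):
        # 1.2 Hz at 11 °C plus the printed 0.9 Hz rise by 21 °C gives ~1.75
        assert np.isclose(endpoint_q10(1.2, 11.0, 2.1, 21.0), 1.75)

    def test_errors(self):
        with pytest.raises(ValueError):
            endpoint_q10(0.0, 11, 1.0, 21)
        with pytest.raises(ValueError):
            endpoint_q10(1.0, 11, 1.0, 11)


class TestConditionDifference:
    def _table(self, mapping):
        return pd.DataFrame(
            {"mean_freq": list(mapping.values())},
            index=pd.Index(list(mapping.keys()), name="target_temp"),
        )

    def test_identical_tables_zero(self):
        t = self._table({11: 1.2, 21: 2.1})
        out = condition_difference(t, t)
        assert np.allclose(out["difference"], 0.0)

    def test_printed_arithmetic(self):
        a = self._table({11: 1.2, 21: 2.1})
        b = self._table({11: 0.9, 21: 1.215})
        out = condition_difference(a, b)
        assert np.allclose(out["difference"].to_numpy(), [0.3, 0.885])
        assert np.isclose(out.attrs["change_a"], 0.9)
        assert np.isclose(out.attrs["change_b"], 0.315)

    def test_mismatched_grid_errors(self):
        a = self._table({11: 1.2, 21: 2.1})
        b = self._table({11: 0.9, 19: 1.1})
        with pytest.raises(ValueError, match="unmatched"):
            condition_difference(a, b)
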