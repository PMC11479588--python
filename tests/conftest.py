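import numpy as np
import pytest

from pylorhythm.simulate import GroundTruth, Protocol, simulate_experiment


@pytest.fixture(scope="session")
def short_protocol() -> Protocol:
    """Three-hold protocol (11/13/15 °C) with shortened holds, for speed."""
    return Protocol(n_steps=2, hold_duration=80.0, initial_hold_duration=60.0,
                    ramp_duration=30.0)


@pytest.fixture(scope="session")
def noiseless_experiment(short_protocol):
    """Deterministic jitter-free experiment with known parameters."""
    gt = GroundTruth.saline(seed=7, spike_jitter_sd=0.0, jag_gain=0.0)
    rec, gt = simulate_experiment(gt, short_protocol)
    return rec, gt


@pytest.fixture(scope="session")
def saline_experiment():
    """Full-protocol saline-like experiment with 5 ms jitter."""
    rec, gt = simulate_experiment(GroundTruth.saline(seed=11))
    return rec, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
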