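import numpy as np
import pytest

from emgfatigue.sigproc import EMGTrace, MUSCLES
from emgfatigue.synth import SimConfig, noise_free


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def nf_config(default_config) -> SimConfig:
    return noise_free(default_config)


@pytest.fixture
def make_trace():
    """Build a single-muscle EMGTrace from a sample array."""

    def _make(samples, rate=2000.0, muscle=MUSCLES[0], t0=0.0, filtered=False):
        return EMGTrace(
            samples=np.asarray(samples, dtype=float),
            rate=rate,
            muscle=muscle,
            t0=t0,
            filtered=filtered,
        )

    return _make


@pytest.fixture(scope="session")
def nf_baseline_session(nf_config):
    """One noise-free baseline session (expensive; shared across tests)."""
    from emgfatigue.synth import generate_baseline_session

    return generate_baseline_session(nf_config, participant_seed=1)


@pytest.fixture(scope="session")
def nf_resistance_trial(nf_config):
    from emgfatigue.synth import generate_constant_power_trial

    return generate_constant_power_trial(nf_config, "resistance", 1)
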