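import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 500.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def strong_connection_trials():
    """High-SNR trials of one connected pair, shared across detection tests."""
    from corticoflow.synthetic_data import ConnectionParams, simulate_connection_trials

    params = ConnectionParams(true_probability=0.8, amplitude=8.0, latency_ms=40.0)
    return simulate_connection_trials(60, params, baseline_s=120.0, seed=7)


@pytest.fixture(scope="session")
def null_connection_trials():
    """Trials of an unconnected pair (noise only)."""
    from corticoflow.synthetic_data import ConnectionParams, simulate_connection_trials

    return simulate_connection_trials(
        60, ConnectionParams(true_probability=0.0), baseline_s=120.0, seed=8
    )
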