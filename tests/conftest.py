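import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    from spheroidsim import SimulationConfig

    return SimulationConfig(
        n_rows=40,
        n_cols=40,
        total_days=2.0,
        initial_radius_sites=5,
        n_replicates=2,
        spontaneous_death_prob=0.0,
    )
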