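import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t2taudit.simulate import SimConfig, simulate_assembly

settings.register_profile(
    "deterministic", deadline=None, derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic genome at seed 1, shared across the suite."""
    config = SimConfig(seed=1)
    assembly, truth = simulate_assembly(config)
    return config, assembly, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
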