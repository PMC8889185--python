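import numpy as np
import pytest

from nestflow import Condition, SimConfig, run_simulation


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A cheap simulation configuration for structural tests."""
    return SimConfig(n_agents=30, n_steps=300, grid_size=20.0, seed=7)


@pytest.fixture(scope="session")
def small_log(small_config):
    return run_simulation(small_config)


@pytest.fixture(scope="session")
def medium_uniform_log():
    """A denser log for network-growth and diffusion tests."""
    return run_simulation(
        SimConfig(n_agents=60, n_steps=1500, grid_size=30.0, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
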