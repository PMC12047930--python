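import numpy as np
import pytest

from eireservoir import ReservoirConfig, build_connectivity


@pytest.fixture(scope="session")
def default_config() -> ReservoirConfig:
    """Standard study configuration: 500 neurons, balanced, theta=0."""
    return ReservoirConfig()


@pytest.fixture(scope="session")
def small_config() -> ReservoirConfig:
    """A 100-neuron reservoir for fast unit tests (same composition)."""
    return ReservoirConfig(n_neurons=100, mean_in_degree=20.0)


@pytest.fixture(scope="session")
def small_conn(small_config):
    return build_connectivity(small_config, rng_seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
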