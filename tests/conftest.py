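import numpy as np
import pytest

from mhcfish import synthetic_data as sd


@pytest.fixture(scope="session")
def base_config():
    return sd.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def resting_population(base_config):
    records, truth = sd.simulate_population(base_config, "resting")
    return records, truth


@pytest.fixture(scope="session")
def activated_population(base_config):
    records, truth = sd.simulate_population(base_config, "activated")
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
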