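import numpy as np
import pytest
from hypothesis import settings

from magfunc.simulate import (SimulationConfig, generate_dataset,
                              generate_module_definitions)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic study at the emulated scale, shared by the suite."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def module_corpus(default_config):
    return generate_module_definitions(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
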