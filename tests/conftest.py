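import numpy as np
import pytest

from ituri.simulate import SimulationConfig, simulate_two_epoch_survey


@pytest.fixture(scope="session")
def default_world():
    """One fully simulated two-epoch study at default design settings."""
    return simulate_two_epoch_survey(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
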