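import numpy as np
import pytest

from netdriver.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_artifacts():
    """One full simulation at the default study conditions, shared read-only."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
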