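import numpy as np
import pytest

from mammosim.core import SimulationConfig, make_initial_state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 40-site 2D lattice: the smallest size hosting the block grid."""
    return SimulationConfig(dims=2, L=40, alpha=(0.1, 0.1, 0.1),
                            lam=(100.0, 50.0, 200.0), seed=7,
                            max_cycles=20)


@pytest.fixture
def small_state(small_config):
    return make_initial_state(small_config)
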