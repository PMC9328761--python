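import numpy as np
import pytest

from dendritic import GeneratorConfig, RatchetParams
from dendritic.simulate import SimParams


@pytest.fixture
def gen_config():
    """Default synthetic-measurement conditions, pinned seed."""
    return GeneratorConfig(seed=0)


@pytest.fixture
def ratchet_params():
    return RatchetParams()


@pytest.fixture
def small_sim():
    """Scaled-down simulation (shorter filaments) for fast stochastic tests."""
    def make(**over):
        defaults = dict(area=1.0, k_on0=20.0, seed=0)
        defaults.update(over)
        return SimParams(**defaults)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
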