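import numpy as np
import pytest

from skm import autoregulatory_network, birth_death_network


@pytest.fixture
def bd_net():
    return birth_death_network(0.03, 0.6)


@pytest.fixture
def ar_net():
    return autoregulatory_network()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
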