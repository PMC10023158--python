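import numpy as np
import pytest

from okretina.synthetic import make_conductance_set, make_stimulus


@pytest.fixture(scope="session")
def default_cset():
    """The packaged synthetic Superior-cell conductance set."""
    return make_conductance_set("Superior", seed=0)


@pytest.fixture(scope="session")
def oscillating_stimulus():
    return make_stimulus("oscillating")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
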