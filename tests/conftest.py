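import numpy as np
import pytest

from permtail import GPDParams, SyntheticSpec, gen_column


@pytest.fixture
def rng():
    return np.random.default_rng(20110411)


@pytest.fixture
def exp_unit_params():
    """GPD reducing to the unit exponential (shape 0, scale 1)."""
    return GPDParams(shape=0.0, scale=1.0)


@pytest.fixture
def exponential_column():
    """N=1000 exponential permutation values with the statistic planted
    at true tail probability 1e-5."""
    return gen_column(SyntheticSpec("exponential", {}, n=1000, seed=3), 1e-5)
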