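import numpy as np
import pytest

from synquant.weights import NormalWeightSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exc_spec():
    """Excitatory reference weight distribution of the cortical microcircuit."""
    return NormalWeightSpec(mean=87.81, std=8.781)


@pytest.fixture
def inh_spec():
    """Inhibitory reference weight distribution of the cortical microcircuit."""
    return NormalWeightSpec(mean=-351.24, std=35.124)


@pytest.fixture
def unit_spec():
    return NormalWeightSpec(mean=0.0, std=1.0)
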