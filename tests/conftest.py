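import numpy as np
import pytest

from quadkin import RateConstants

# Published kinetic regimes of the two variants whose transition was fitted.
WT22M_RATES = RateConstants(k1=0.23, k2=533.0, k3=50.0, k4=0.037, k5=2.7e-4)
FC4_RATES = RateConstants(k1=0.58, k2=653.0, k3=73.0, k4=0.027, k5=0.023)


@pytest.fixture
def wt22m_rates():
    return WT22M_RATES


@pytest.fixture
def fc4_rates():
    return FC4_RATES


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
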