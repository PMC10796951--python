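import numpy as np
import pytest

from fracliver.datasets import table1_params
from fracliver.model import FractionalConfig


@pytest.fixture(scope="session")
def params():
    """Clinical kinetic parameter set (alpha, beta, delta, R0=250, W0=0)."""
    return table1_params()


@pytest.fixture(scope="session")
def frac63():
    """Pinned fractional configuration: order 0.63, rho = 1 min, M = 1."""
    return FractionalConfig(0.63)


@pytest.fixture(scope="session")
def blood_times():
    """The clinical blood sampling grid (minutes)."""
    return np.array([0.0, 3.0, 5.0, 10.0, 20.0, 30.0, 43.0])
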