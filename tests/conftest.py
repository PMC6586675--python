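import numpy as np
import pytest

from ribotrace.synthetic_data import (NoiseModel, c_domain_scheme,
                                      rnc_misfold_scheme)
from ribotrace.tether_mechanics import DEFAULT_MODEL


@pytest.fixture(scope="session")
def model():
    return DEFAULT_MODEL


@pytest.fixture(scope="session")
def noise():
    """Instrument noise: 0.25 pN at 1333 Hz, white Gaussian."""
    return NoiseModel()


@pytest.fixture(scope="session")
def quiet():
    return NoiseModel(sd_at_reference=0.0)


@pytest.fixture(scope="session")
def misfold_scheme():
    """Stalled-RNC two-state scheme: unfolded lifetime 1.5 s at 4.0 pN."""
    return rnc_misfold_scheme()


@pytest.fixture(scope="session")
def cdomain_scheme():
    return c_domain_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
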