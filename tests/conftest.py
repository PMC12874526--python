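import numpy as np
import pytest

from whiteflysim.config import default_model_params
from whiteflysim.deb import derive_compound_params


@pytest.fixture(scope="session")
def params():
    """Shipped default parameter bundle (ModelParams)."""
    return default_model_params()


@pytest.fixture(scope="session")
def deb(params):
    return params.deb


@pytest.fixture(scope="session")
def comp(deb):
    """Derived DEB compound parameters (E_0, L_b, L_p, ...)."""
    return derive_compound_params(deb)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
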