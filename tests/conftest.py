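import numpy as np
import pytest

from cellforce.model_core import DimensionlessParams, GridSpec


@pytest.fixture(scope="session")
def grid32():
    return GridSpec(n=32)


@pytest.fixture(scope="session")
def grid64():
    return GridSpec(n=64)


@pytest.fixture(scope="session")
def grid256():
    return GridSpec(n=256)


@pytest.fixture
def params_small():
    """Well-resolved, stable parameter set for small control problems."""
    return DimensionlessParams(eps_bar=0.08, tau_bar=2.0, delta_bar=1.0, theta=1e-3, RTS=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
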