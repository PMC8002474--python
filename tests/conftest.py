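import numpy as np
import pytest

from stickytube import ChainParams, scaled_params


@pytest.fixture(scope="session")
def silk() -> ChainParams:
    """The silk feedstock parameter set (physical units)."""
    return ChainParams()


@pytest.fixture(scope="session")
def silk_scaled() -> ChainParams:
    """Desk-scale silk parameters (reduced time units, tau_s0/tau_e = 100)."""
    return scaled_params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
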