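import numpy as np
import pytest

from sirnatraffic import Protocol, TraffickingParams, simulate


@pytest.fixture(scope="session")
def params():
    return TraffickingParams()


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def default_trajectory(params, protocol):
    """One 20 nM / 6 h-transfect / 24 h run shared by read-only tests."""
    return simulate(protocol, params)


@pytest.fixture(scope="session")
def control_trajectory(params, protocol):
    return simulate(protocol.with_(dose=0.0), params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
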