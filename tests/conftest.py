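import numpy as np
import pytest

from stripesim.motility import motility_tables
from stripesim.params import (GrowthFieldParams, MotilityParams,
                              SignalingParams)


@pytest.fixture(scope="session")
def sp():
    return SignalingParams()


@pytest.fixture(scope="session")
def mp():
    return MotilityParams()


@pytest.fixture(scope="session")
def gp():
    return GrowthFieldParams()


@pytest.fixture(scope="session")
def tables():
    """Shared steady-state lookup tables (expensive to build)."""
    return motility_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
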