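import numpy as np
import pytest

from androscape import (
    DEFAULT_GROWTH_PARAMS,
    DEFAULT_KINETIC_PARAMS,
    build_state_grid,
)


@pytest.fixture(scope="session")
def kp():
    """Baseline kinetic parameters."""
    return DEFAULT_KINETIC_PARAMS


@pytest.fixture(scope="session")
def gp():
    """Baseline growth parameters."""
    return DEFAULT_GROWTH_PARAMS


@pytest.fixture(scope="session")
def grid():
    """Default 100-state AR-expression grid (15..114 nM)."""
    return build_state_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
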