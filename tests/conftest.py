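import numpy as np
import pytest

from il35sim import (
    ScalingSystem,
    build_grid,
    load_scenario,
    nondimensionalize,
)
from il35sim.runlib import default_initial_state


@pytest.fixture(scope="session")
def params_il35():
    return load_scenario("J558-IL-35")


@pytest.fixture(scope="session")
def params_ctrl():
    return load_scenario("J558-Ctrl")


@pytest.fixture(scope="session")
def scaling():
    return ScalingSystem()


@pytest.fixture(scope="session")
def p_nd(params_il35, scaling):
    """Dimensionless J558-IL-35 parameter set (what the solver integrates)."""
    return nondimensionalize(params_il35, scaling)


@pytest.fixture(scope="session")
def grid32(p_nd):
    return build_grid(p_nd.R_domain, 32)


@pytest.fixture(scope="session")
def ic32(p_nd, grid32):
    return default_initial_state(p_nd, grid32)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)
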