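import numpy as np
import pytest

from nacsim.grid import make_grid
from nacsim.pharmacodynamics import PDParams
from nacsim.scenario import synth_scenario


@pytest.fixture(scope="session")
def grid16():
    return make_grid((16, 16, 16), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def grid10():
    return make_grid((10, 10, 10), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def well_scenario(grid16):
    """The well-perfused tissue box used throughout: 32 mm cube, 8 mm
    spherical tumor at 60% of carrying capacity."""
    return synth_scenario(grid16, 8.0, 0.6, "well", 2.0, seed=1)


@pytest.fixture(scope="session")
def small_scenario(grid10):
    """A smaller box for cheap end-to-end runs."""
    return synth_scenario(grid10, 4.0, 0.6, "well", 2.0, seed=3)


@pytest.fixture()
def pd_params():
    return PDParams(rho0=0.025, h1=2.0, h2=1.5, C1=0.01, C2=10.0,
                    E1n=-2.0, E2n=0.3, a1=3.0, a2=0.5, beta=0.1)


def rng(seed=0):
    return np.random.default_rng(seed)
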