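import numpy as np
import pytest

from msdager import simulator
from msdager.scheme import two_shell_scheme


@pytest.fixture(scope="session")
def small_grid():
    return (4, 36, 32)


@pytest.fixture(scope="session")
def phantom(small_grid):
    return simulator.make_phantom(simulator.PhantomSpec(grid_shape=small_grid), seed=0)


@pytest.fixture(scope="session")
def coils(small_grid):
    return simulator.make_coil_sensitivities(small_grid, n_coils=8, seed=1)


@pytest.fixture(scope="session")
def scheme36():
    """Two-shell 36-direction scheme with one b=0 volume."""
    return two_shell_scheme(18, n_b0=1, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
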