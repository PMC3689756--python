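import numpy as np
import pytest

from dipoletrack import GridSpec, TankGeometry, build_grid, build_lut, make_configuration
from dipoletrack.lut import DEFAULT_FISH_LENGTH


@pytest.fixture(scope="session")
def tank():
    return TankGeometry()


@pytest.fixture(scope="session")
def array8(tank):
    return make_configuration("8P67.5", tank)


@pytest.fixture(scope="session")
def small_tank():
    """Reduced arena for fast grid/LUT tests."""
    return TankGeometry(radius=30.0)


@pytest.fixture(scope="session")
def small_array(small_tank):
    return make_configuration("8P67.5", small_tank)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(
        coarse_xy_step=4.0,
        coarse_theta_step=12.0,
        fine_xy_step=1.0,
        fine_theta_step=3.0,
        wall_band=6.0,
    )


@pytest.fixture(scope="session")
def small_fish_length():
    return 10.0


@pytest.fixture(scope="session")
def small_lut(small_array, small_tank, small_grid, small_fish_length):
    nodes = build_grid(small_tank, small_grid, small_fish_length)
    return build_lut(small_array, small_tank, nodes, small_grid, small_fish_length)


@pytest.fixture(scope="session")
def full_lut(array8, tank):
    """Production-scale coarse LUT (2 cm / 4 deg, wall-densified)."""
    grid = GridSpec()
    nodes = build_grid(tank, grid, DEFAULT_FISH_LENGTH)
    return build_lut(array8, tank, nodes, grid, DEFAULT_FISH_LENGTH)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
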