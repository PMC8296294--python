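import numpy as np
import pytest

from swimdyn import FluidEnvironment, coefficient_grid
from swimdyn.io import fixture_path, read_resistance_grid


@pytest.fixture(scope="session")
def water():
    return FluidEnvironment()


@pytest.fixture(scope="session")
def resistance_grid():
    """The packaged palm resistance grid (5 speeds x 4 spread angles)."""
    return read_resistance_grid(fixture_path("palm_resistance_grid.csv"))


@pytest.fixture(scope="session")
def printed_coefficients():
    """The published coefficient grid corresponding to the resistance grid."""
    grid = read_resistance_grid(fixture_path("palm_coefficient_grid.csv"))
    return grid.resistance  # same CSV layout; cells are coefficients


@pytest.fixture(scope="session")
def computed_grid(resistance_grid, water):
    return coefficient_grid(resistance_grid, water)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
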