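import numpy as np
import pytest

from tmscan import FreqSweep, GridSpec, build_array, enumerate_paths


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 60 x 40 mm grid used for fast physics tests."""
    return GridSpec(60.0, 40.0, 2.0)


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()


@pytest.fixture(scope="session")
def sweep():
    return FreqSweep()


@pytest.fixture(scope="session")
def small_paths(small_grid):
    """A modest path set over the small grid (separation fixed per test)."""
    geom = build_array(small_grid, d_mm=50.0)
    return enumerate_paths(geom)[::150]  # ~180 paths spread over the aperture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
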