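import numpy as np
import pytest

from dcefit.aif import parker_aif

DT_MIN = 0.5 / 60.0  # 0.5 s sampling


@pytest.fixture(scope="session")
def time_grid():
    """10-minute acquisition at 0.5 s resolution."""
    return DT_MIN * np.arange(int(round(10.0 / DT_MIN)) + 1)


@pytest.fixture(scope="session")
def coarse_time_grid():
    """2-minute grid at 1 s resolution for cheap fitting tests."""
    dt = 1.0 / 60.0
    return dt * np.arange(121)


@pytest.fixture(scope="session")
def population_aif(time_grid):
    return parker_aif(time_grid, onset_min=1.0)


@pytest.fixture(scope="session")
def coarse_aif(coarse_time_grid):
    return parker_aif(coarse_time_grid, onset_min=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
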