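import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bayfate.grid import SEA, BayGrid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_cfl_warnings():
    """The coarse test grids intentionally run above the explicit CFL."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def closed_basin(nx=24, ny=8, dx=400.0, dy=300.0, depth=10.0):
    """A fully closed rectangular basin (no open boundary) for conservation
    testing."""
    return BayGrid(
        nx=nx, ny=ny, dx=dx, dy=dy,
        H=np.full((nx, ny), depth),
        mask=np.full((nx, ny), SEA, dtype=np.int8),
    )


@pytest.fixture
def basin():
    return closed_basin()
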