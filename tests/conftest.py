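import numpy as np
import pytest

from restconn.grid import VolumeGrid
from restconn.prep import FmriSession


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VolumeGrid((8, 8, 8), (3.0, 3.0, 3.0), (-10.5, -10.5, -10.5))


@pytest.fixture
def session_factory(small_grid):
    """Build small sessions with arbitrary data for unit tests."""

    def make(data=None, t=40, seed=0, grid=None, tr_s=2.0, condition="abstinence"):
        g = grid or small_grid
        if data is None:
            data = np.random.default_rng(seed).standard_normal(g.dims + (t,))
        return FmriSession("sub-001", condition, g, tr_s, data)

    return make
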