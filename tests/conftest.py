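import numpy as np
import pytest

from treeline_drivers.raster import RasterGrid
from treeline_drivers.synthetic import SyntheticTruth, simulate_scene


def make_grid(values, cell_size=1.0, origin=(0.0, 0.0)) -> RasterGrid:
    return RasterGrid(np.asarray(values, dtype=float), cell_size=cell_size, origin=origin)


@pytest.fixture(scope="session")
def small_scene() -> dict:
    """A 64x64 synthetic scene with default drivers, shared across tests."""
    truth = SyntheticTruth(seed=7, nrows=64, ncols=64)
    return simulate_scene(truth, diagnostics=True)
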