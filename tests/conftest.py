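import numpy as np
import pytest

from coastsdm.bioclim import compute_bioclim, window_average
from coastsdm.grids import GridSpec, RasterGrid
from coastsdm.synthetic import ClimateScenario, generate_climate


def make_grid(values, west=-90.0, south=10.0, cell=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        west=west,
        south=south,
        cell_size=cell,
        nodata=nodata,
    )
    return RasterGrid(spec, values)


@pytest.fixture
def spec_4x4():
    return GridSpec(n_rows=4, n_cols=4, west=-90.0, south=10.0, cell_size=1.0)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact synthetic world shared by the slower model tests."""
    grid = GridSpec(n_rows=40, n_cols=50, west=-95.0, south=0.0, cell_size=0.6)
    return ClimateScenario(grid=grid, seed=7)


@pytest.fixture(scope="session")
def present_stack(small_scenario):
    series = generate_climate(small_scenario, range(2013, 2019))
    normals = window_average(series, (2013, 2018))
    return compute_bioclim(normals)
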