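import numpy as np
import pytest

import sdmconnect as sc
from sdmconnect.raster import RasterGrid


@pytest.fixture(scope="session")
def default_run() -> sc.PipelineResult:
    """One full pipeline replay under the default study conditions
    (150x150 landscape, 80 presences, seed 1), shared across tests."""
    return sc.run_all(sc.PipelineConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_grid(values, cell_size=1000.0, nodata=-9999.0, name="g") -> RasterGrid:
    return RasterGrid(
        np.asarray(values, dtype=float),
        x_min=0.0,
        y_min=0.0,
        cell_size=cell_size,
        nodata=nodata,
        name=name,
    )
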