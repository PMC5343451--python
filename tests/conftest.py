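import numpy as np
import pytest
from shapely.geometry import Polygon

from pigdensity.raster import RasterGrid
from pigdensity.synthetic import CovariateFieldSpec, LandscapeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_specs():
    return [
        CovariateFieldSpec("pet", "abiotic-climate", 60.0, (200.0, 2000.0), outward_trend=-0.5),
        CovariateFieldSpec("carnivore", "biotic-predation", 80.0, (0.0, 6.0),
                           integer_valued=True, outward_trend=0.5),
        CovariateFieldSpec("agriculture", "biotic-vegetation", 40.0, (0.0, 1.0)),
    ]


@pytest.fixture
def small_landscape(small_specs):
    """A fast 60x60 landscape (1200 km at 20 km cells)."""
    return LandscapeConfig(
        seed=7,
        extent=(1200.0, 1200.0),
        cell_size=20.0,
        covariate_specs=small_specs,
        island_fraction=0.02,
    )


@pytest.fixture
def square_polygon():
    return Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])


@pytest.fixture
def random_grid(rng):
    return RasterGrid(rng.normal(size=(12, 15)), xllcorner=0.0, yllcorner=0.0, cell_size=2.0)
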