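import numpy as np
import pytest

from isomigrate import RangeMask, RasterGrid, WorldConfig, make_world
from isomigrate.synthetic import PhenologyModel, PrecipModel, TissueModel


def make_grid(values, origin_lon=0.0, origin_lat=0.0, cell=1.0,
              nodata=-9999.0):
    """Small top-down grid helper used across test modules."""
    values = np.asarray(values, dtype=float)
    return RasterGrid(
        values=values,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size_lon=cell,
        cell_size_lat=-cell,
        nodata_value=nodata,
    )


def full_mask(grid):
    return RangeMask(grid.with_values(np.ones(grid.shape)))


@pytest.fixture
def small_world_config():
    """A coarse 30x20 domain that keeps simulation tests fast."""
    return WorldConfig(
        lat_range=(25.0, 55.0),
        lon_range=(-95.0, -75.0),
        resolution=1.0,
        rng_seed=42,
    )


@pytest.fixture
def small_world(small_world_config):
    return make_world(small_world_config)


@pytest.fixture
def noiseless_config():
    """Latitude-only precipitation signal with zero noise everywhere."""
    return WorldConfig(
        lat_range=(30.0, 50.0),
        lon_range=(-90.0, -80.0),
        resolution=1.0,
        precip_model=PrecipModel(intercept=-10.0, lat_slope=-1.5,
                                 lon_slope=0.0, elev_slope=0.0,
                                 temp_slope=0.0, resid_sd=0.0),
        tissue_model=TissueModel(intercept=0.0, slope=1.0, site_sd=0.0),
        phenology_model=PhenologyModel(resid_sd=0.0),
        rng_seed=7,
    )
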