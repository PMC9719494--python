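import warnings

import numpy as np
import pandas as pd
import pytest

from poleward.coastal_geometry import build_coast_geometry
from poleward.extremes import build_climatology
from poleward.grid_io import GridField, GridSeries
from poleward.predictors import PredictorContext
from poleward.synthetic_data import SynthConfig, make_cohort, make_world
from poleward.thermal_change import velocity_from_monthly


def monthly_series(values, lat, lon, start="2000-01", landmask=None, units="degC"):
    """Helper: wrap a (t, lat, lon) array as a monthly GridSeries."""
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=values.shape[0], freq="MS") + pd.Timedelta(days=14)
    return GridSeries(values, np.asarray(lat, float), np.asarray(lon, float), times, "monthly",
                      landmask=landmask, units=units)


def daily_series(values, lat, lon, start="2000-01-01", landmask=None, units="degC"):
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=values.shape[0], freq="D")
    return GridSeries(values, np.asarray(lat, float), np.asarray(lon, float), times, "daily",
                      landmask=landmask, units=units)


@pytest.fixture(scope="session")
def small_config():
    """A 14-year, ~33x13-cell world that runs the whole pipeline in seconds."""
    return SynthConfig(
        seed=3,
        lat_min=-40.0,
        lat_max=-32.0,
        lon_min=147.0,
        lon_max=150.0,
        start_year=1996,
        end_year=2009,
        baseline=(1996, 2005),
        velocity_window=(1996, 2009),
        obs_years=(2006, 2009),
        n_species=8,
        n_records=14,
        limit_lat_range=(-33.5, -36.5),
        mhw_schedule=((2007, 2, -36.0, -34.0, 2.5),),
        mcs_schedule=((2008, 150, 8, -37.0, -35.0, 3.0),),
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def small_velocity(small_world, small_config):
    return velocity_from_monthly(small_world.sst_monthly, small_config.velocity_window)


@pytest.fixture(scope="session")
def small_climatology(small_world, small_config):
    return build_climatology(small_world.sst_daily, small_config.baseline)


@pytest.fixture(scope="session")
def small_geometry(small_world):
    return build_coast_geometry(small_world.landmask)


@pytest.fixture(scope="session")
def small_context(small_world, small_config, small_velocity, small_climatology, small_geometry):
    return PredictorContext(
        small_geometry,
        small_velocity,
        small_world.u_series,
        small_world.v_series,
        small_world.sst_monthly,
        small_world.sst_daily,
        small_climatology,
        (small_config.start_year, small_config.end_year),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, small_world, small_geometry, small_context):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_cohort(small_config, small_world, small_geometry, small_context)
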