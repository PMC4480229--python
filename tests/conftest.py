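"""Shared fixtures: small idealized scenarios and steady forcing fields."""

import numpy as np
import pytest

import pleuston as pl

FAR_PAST = "2009-01-01"
FAR_FUTURE = "2011-01-01"


def steady_wind(bounds, u, v):
    """Spatially uniform, steady wind on a coarse 2x2 grid over ``bounds``."""
    g = pl.GridSpec(*bounds, 2, 2, [FAR_PAST])
    if u == 0 and v == 0:
        return pl.make_wind_field(g, [])
    return pl.make_wind_field(g, [(FAR_PAST, FAR_FUTURE, u, v)])


def bounds_of(grid):
    return (grid.lon_min, grid.lon_max, grid.lat_min, grid.lat_max)


@pytest.fixture(scope="session")
def coast_scenario():
    """Open coast: land along the northern edge, 0.05 deg cells."""
    grid = pl.GridSpec(0.0, 4.0, 34.0, 36.0, 81, 41, ["2010-01-01"])
    return pl.make_scenario("open_coast", grid)


@pytest.fixture(scope="session")
def gyre_scenario():
    """Closed basin for gyre experiments, centred near 36 N."""
    grid = pl.GridSpec(-8.0, -4.0, 34.0, 38.0, 101, 101, ["2010-01-01"])
    return pl.make_scenario("single_gyre_basin", grid)


@pytest.fixture(scope="session")
def two_basin_scenario():
    """Two-basin / strait domain used by the transport experiments."""
    grid = pl.GridSpec(-10.0, 0.0, 34.0, 38.0, 200, 100, ["2010-01-15", "2010-03-30"])
    return pl.make_scenario("two_basin_strait", grid)


@pytest.fixture(scope="session")
def still_coast_env(coast_scenario):
    """Open-coast environment with zero currents and zero wind."""
    cur = pl.make_current_field(coast_scenario, "uniform", u=0.0, v=0.0)
    wind = steady_wind(bounds_of(coast_scenario.grid), 0.0, 0.0)
    return pl.Environment(coast_scenario, cur, wind)
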