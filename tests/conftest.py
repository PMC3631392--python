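import numpy as np
import pytest

from nichecast.climate_derive import derive_covariates
from nichecast.geo_io import Grid
from nichecast.synthetic_data import make_climate, make_study_fixture, make_terrain


@pytest.fixture(scope="session")
def study():
    """Full-size default study fixture (17 species on a 100x100 landscape)."""
    return make_study_fixture(7)


@pytest.fixture(scope="session")
def landscape():
    """Small bare landscape (no forest): dem + current covariate stack."""
    dem = make_terrain(3, 60, 60)
    mc = make_climate(dem, 4)
    return {"dem": dem, "climate": mc, "stack": derive_covariates(mc)}


@pytest.fixture()
def tiny_grid():
    """3x3 grid with one nodata cell, origin (10, -20), half-degree cells."""
    values = np.arange(9, dtype=float).reshape(3, 3)
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    values[1, 1] = np.nan
    return Grid(values, 10.0, -20.0, 0.5, mask)
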