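"""Shared fixtures: small, fast synthetic worlds and their cell tables."""

import numpy as np
import pytest

from gridbias import TrueNiche, WorldSpec, make_world
from gridbias.gridding import aggregate_to_grid, grid_for_world, land_cells


@pytest.fixture(scope="session")
def small_spec():
    # 0.5 degree world on a reduced band: fast but structurally complete
    return WorldSpec(
        seed=11,
        fine_resolution=0.5,
        lat_extent=(20.0, 80.0),
        lon_extent=(-60.0, 60.0),
        land_fraction_target=0.5,
    )


@pytest.fixture(scope="session")
def small_niche():
    return TrueNiche(
        intercept=1.0,
        linear_coefs=(-2.5, 0.2, 0.3, -0.2),
        quadratic_coefs=(-0.5, -0.05, -0.1, -0.05),
        nuisance_amplitude=1.5,
        nuisance_correlation_length=15.0,
    )


@pytest.fixture(scope="session")
def small_world(small_spec, small_niche):
    return make_world(small_spec, small_niche)


@pytest.fixture(scope="session")
def longlat_table(small_world):
    grid = grid_for_world(small_world.spec, "longlat", 2.0)
    return aggregate_to_grid(small_world, grid)


@pytest.fixture(scope="session")
def equalarea_table(small_world):
    grid = grid_for_world(small_world.spec, "equalarea", 200.0)
    return aggregate_to_grid(small_world, grid)


@pytest.fixture(scope="session")
def longlat_land(longlat_table):
    return land_cells(longlat_table)


@pytest.fixture(scope="session")
def equalarea_land(equalarea_table):
    return land_cells(equalarea_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
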