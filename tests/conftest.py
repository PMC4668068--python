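import numpy as np
import pytest

from savannafire import (
    FireHistory,
    GridGeometry,
    LandscapeUnits,
    full_lowland_units,
    synthetic_units,
)


@pytest.fixture
def grid4():
    return GridGeometry(4, 4)


@pytest.fixture
def grid30():
    return GridGeometry(30, 30)


def random_history(grid, n_years=5, p_eds=0.15, p_lds=0.2, seed=0, start_year=2000):
    """Bernoulli-pixel fire history (no spatial structure) for oracle tests."""
    rng = np.random.default_rng(seed)
    eds = (rng.random((n_years, *grid.shape)) < p_eds).astype(np.uint8)
    lds = (rng.random((n_years, *grid.shape)) < p_lds).astype(np.uint8)
    return FireHistory(grid, list(range(start_year, start_year + n_years)), eds, lds)


def history_from_year_masks(grid, eds_by_year, lds_by_year, start_year=2000):
    """Build a FireHistory from explicit per-year masks (lists of 2D arrays)."""
    eds = np.stack([np.asarray(m, dtype=np.uint8) for m in eds_by_year])
    lds = np.stack([np.asarray(m, dtype=np.uint8) for m in lds_by_year])
    years = list(range(start_year, start_year + len(eds_by_year)))
    return FireHistory(grid, years, eds, lds)


@pytest.fixture
def units30(grid30):
    return synthetic_units(grid30, upland_fraction=0.3)


@pytest.fixture
def lowland30(grid30):
    return full_lowland_units(grid30)
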