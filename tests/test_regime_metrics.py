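import numpy as np
import pytest

from savannafire import (
    AssessmentWindow,
    GridGeometry,
    Unit,
    full_lowland_units,
    long_unburnt_proportion,
    seasonal_frequency,
    time_since_last_burnt,
)
from _oracles import (
    per_pixel_annual_frequency,
    per_pixel_tslb,
    per_pixel_unburnt_proportion,
)
from conftest import history_from_year_masks, random_history

W5 = AssessmentWindow(2000, 5)


def test_frequency_of_alternating_full_lds_burns(grid4):
    """Unit fully burnt in LDS of years 1, 3, 5 only: LDS mean 0.6, EDS 0,
    annual SEM = sd({1,0,1,0,1})/sqrt(5)."""
    ones, zeros = np.ones(grid4.shape), np.zeros(grid4.shape)
    h = history_from_year_masks(
        grid4, [zeros] * 5, [ones, zeros, ones, zeros, ones]
    )
    f = seasonal_frequency(h, full_lowland_units(grid4), W5)[Unit.LOWLAND]
    assert f.mean["LDS"] == pytest.approx(0.6)
    assert f.mean["EDS"] == 0.0
    assert f.mean["ANNUAL"] == pytest.approx(0.6)
    expected_sem = np.std([1, 0, 1, 0, 1], ddof=1) / np.sqrt(5)
    assert f.sem["ANNUAL"] == pytest.approx(expected_sem)
    assert expected_sem == pytest.approx(0.245, abs=0.001)


def test_never_burnt_unit_reports_zero_frequency(grid4):
    zeros = np.zeros(grid4.shape)
    h = history_from_year_masks(grid4, [zeros] * 5, [zeros] * 5)
    f = seasonal_frequency(h, full_lowland_units(grid4), W5)[Unit.LOWLAND]
    assert all(v == 0.0 for v in f.mean.values())
    assert all(v == 0.0 for v in f.sem.values())


@pytest.mark.parametrize("seed", range(3))
def test_frequency_matches_per_pixel_brute_force(grid30, units30, seed):
    """The per-year unit-fraction mean equals the per-pixel burnt-year-count
    mean exactly (the two computations the definition equates)."""
    h = random_history(grid30, n_years=5, seed=seed)
    freq = seasonal_frequency(h, units30, W5)
    for unit in (Unit.LOWLAND, Unit.UPLAND):
        oracle = per_pixel_annual_frequency(h, units30.unit_mask(unit), W5.years)
        assert freq[unit].mean["ANNUAL"] == pytest.approx(oracle, abs=1e-12)


def test_annual_frequency_bounded_by_seasonal(grid30, units30):
    """max(EDS, LDS) <= ANNUAL <= EDS + LDS (union bound), every unit."""
    for seed in range(5):
        h = random_history(grid30, n_years=5, seed=100 + seed)
        for f in seasonal_frequency(h, units30, W5).values():
            assert f.mean["ANNUAL"] >= max(f.mean["EDS"], f.mean["LDS"]) - 1e-12
            assert f.mean["ANNUAL"] <= f.mean["EDS"] + f.mean["LDS"] + 1e-12


def test_empty_unit_is_flagged_not_nan_crash(grid4):
    zeros = np.zeros(grid4.shape)
    h = history_from_year_masks(grid4, [zeros] * 5, [zeros] * 5)
    units = full_lowland_units(grid4)  # no upland pixels
    f = seasonal_frequency(h, units, W5)
    assert not f[Unit.UPLAND].valid
    assert f[Unit.LOWLAND].valid


class TestTimeSinceLastBurnt:
    def _single_pixel_history(self, grid4, burn_years, season="EDS", n_years=5):
        eds, lds = [], []
        for y in range(2000, 2000 + n_years):
            m = np.zeros(grid4.shape)
            if y in burn_years:
                m[0, 0] = 1
            eds.append(m if season == "EDS" else np.zeros(grid4.shape))
            lds.append(m if season == "LDS" else np.zeros(grid4.shape))
        return history_from_year_masks(grid4, eds, lds)

    def test_burn_four_years_ago(self, grid4):
        h = self._single_pixel_history(grid4, {2000})
        t = time_since_last_burnt(h, 2004)
        assert t.years[0, 0] == 4 and not t.censored[0, 0]

    def test_burn_in_assessment_year_is_zero(self, grid4):
        h = self._single_pixel_history(grid4, {2004})
        t = time_since_last_burnt(h, 2004)
        assert t.years[0, 0] == 0

    def test_never_burnt_is_censored_at_history_depth(self, grid4):
        h = self._single_pixel_history(grid4, set())
        t = time_since_last_burnt(h, 2004)
        assert t.censored[0, 0]
        assert t.years[0, 0] == 5  # read as ">= 5"

    @pytest.mark.parametrize("as_of", [2002, 2004])
    def test_matches_backwards_scan_oracle(self, as_of):
        grid = GridGeometry(8, 8)
        h = random_history(grid, n_years=5, seed=42)
        t = time_since_last_burnt(h, as_of)
        oracle = per_pixel_tslb(h, as_of)
        for (r, c), expected in oracle.items():
            if expected is None:
                assert t.censored[r, c]
            else:
                assert t.years[r, c] == expected


class TestLongUnburnt:
    def test_half_always_burnt_half_never(self, grid4):
        m = np.zeros(grid4.shape)
        m[:2] = 1  # top half burns every year
        h = history_from_year_masks(grid4, [m] * 5, [np.zeros(grid4.shape)] * 5)
        u = long_unburnt_proportion(h, full_lowland_units(grid4), 2004)[Unit.LOWLAND]
        assert u.proportion_unburnt_ge3 == 0.5
        assert u.proportion_unburnt_ge5 == 0.5

    def test_lookback_includes_the_assessment_year(self, grid4):
        """All burnt in 2002 only: ge3 as of 2004 is 0 (2002 in lookback);
        as of 2005 it is 1 (lookback 2003-2005)."""
        masks = [np.ones(grid4.shape) if y == 2002 else np.zeros(grid4.shape)
                 for y in range(2000, 2006)]
        h = history_from_year_masks(grid4, masks, [np.zeros(grid4.shape)] * 6)
        units = full_lowland_units(grid4)
        u04 = long_unburnt_proportion(h, units, 2004, min_years_list=(3,))[Unit.LOWLAND]
        assert u04.proportion_unburnt_ge3 == 0.0
        u05 = long_unburnt_proportion(h, units, 2005, min_years_list=(3,))[Unit.LOWLAND]
        assert u05.proportion_unburnt_ge3 == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, grid30, units30, seed):
        h = random_history(grid30, n_years=6, p_eds=0.1, p_lds=0.15, seed=seed)
        res = long_unburnt_proportion(h, units30, 2005)
        for unit in (Unit.LOWLAND, Unit.UPLAND):
            for m, got in ((3, res[unit].proportion_unburnt_ge3),
                           (5, res[unit].proportion_unburnt_ge5)):
                oracle = per_pixel_unburnt_proportion(h, units30.unit_mask(unit), 2005, m)
                assert got == pytest.approx(oracle, abs=1e-12)

    def test_ge5_never_exceeds_ge3(self, grid30, units30):
        for seed in range(5):
            h = random_history(grid30, n_years=5, seed=200 + seed)
            for u in long_unburnt_proportion(h, units30, 2004).values():
                assert u.proportion_unburnt_ge5 <= u.proportion_unburnt_ge3 + 1e-12

    def test_everything_burnt_every_year_leaves_nothing_unburnt(self, grid4):
        ones = np.ones(grid4.shape)
        h = history_from_year_masks(grid4, [ones] * 5, [np.zeros(grid4.shape)] * 5)
        units = full_lowland_units(grid4)
        f = seasonal_frequency(h, units, W5)[Unit.LOWLAND]
        assert f.mean["ANNUAL"] == 1.0
        u = long_unburnt_proportion(h, units, 2004)[Unit.LOWLAND]
        assert u.proportion_unburnt_ge3 == 0.0

    def test_insufficient_depth_raises_with_required_depth(self, grid4):
        zeros = np.zeros(grid4.shape)
        h = history_from_year_masks(grid4, [zeros] * 3, [zeros] * 3)
        with pytest.raises(ValueError, match="5"):
            long_unburnt_proportion(h, full_lowland_units(grid4), 2002)
        # a 3-year lookback alone is fine with 3 years of history
        res = long_unburnt_proportion(
            h, full_lowland_units(grid4), 2002, min_years_list=(3,)
        )
        assert res[Unit.LOWLAND].proportion_unburnt_ge3 == 1.0
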