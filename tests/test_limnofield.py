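"""Profile interpolation, isocline depths, and habitat masks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxytherm as ox
from oxytherm.limnofield import DISSOLVED_OXYGEN, TEMPERATURE


def cast(depths, values, variable=TEMPERATURE, when="2015-06-01"):
    return ox.ProfileCast(pd.Timestamp(when), variable, np.asarray(depths, float),
                          np.asarray(values, float))


class TestVerticalInterpolation:
    def test_linear_midpoint_and_node_identity(self):
        col, flagged = ox.interpolate_vertical(cast([0, 10], [20, 10]),
                                               grid=np.arange(0, 10.1, 0.1))
        assert col[50] == pytest.approx(15.0)  # 5.0 m
        assert col[0] == pytest.approx(20.0)
        assert col[100] == pytest.approx(10.0)
        assert not flagged

    def test_piecewise_segments(self):
        col, _ = ox.interpolate_vertical(cast([0, 1, 2], [8, 8, 2]),
                                         grid=np.arange(0, 2.1, 0.1))
        assert col[15] == pytest.approx(5.0)  # 1.5 m

    def test_single_sample_holds_constant_with_flag(self):
        col, flagged = ox.interpolate_vertical(cast([5], [7.0]),
                                               grid=np.arange(0, 10.1, 0.1))
        assert np.all(col == 7.0)
        assert flagged

    def test_edge_hold_below_cast_is_flagged(self):
        col, flagged = ox.interpolate_vertical(cast([0, 5], [10, 6]),
                                               grid=np.arange(0, 10.1, 0.1))
        assert col[-1] == pytest.approx(6.0)
        assert flagged

    def test_empty_cast_rejected(self):
        with pytest.raises(ValueError):
            cast([], [])


class TestTemporalInterpolation:
    def test_midpoint_between_casts(self):
        casts = [cast([0, 10], [8, 8], DISSOLVED_OXYGEN, "2015-06-01"),
                 cast([0, 10], [4, 4], DISSOLVED_OXYGEN, "2015-06-11")]
        field = ox.interpolate_temporal(casts, grid=np.arange(0, 10.1, 0.1))
        assert field.values[30, 5] == pytest.approx(6.0)  # day 5
        assert not field.flags[5]

    def test_piecewise_in_time(self):
        casts = [cast([0, 10], [9, 9], DISSOLVED_OXYGEN, "2015-06-01"),
                 cast([0, 10], [5, 5], DISSOLVED_OXYGEN, "2015-06-05"),
                 cast([0, 10], [5, 5], DISSOLVED_OXYGEN, "2015-06-09")]
        field = ox.interpolate_temporal(casts, grid=np.arange(0, 10.1, 0.1))
        assert field.values[0, 2] == pytest.approx(7.0)  # between first two casts
        assert field.values[0, 7] == pytest.approx(5.0)  # between last two

    def test_single_cast_held_constant_and_flagged(self):
        times = pd.date_range("2015-06-01", periods=5, freq="D")
        field = ox.interpolate_temporal(
            [cast([0, 10], [8, 2], DISSOLVED_OXYGEN, "2015-06-03")],
            times=times, grid=np.arange(0, 10.1, 0.1))
        assert np.all(field.values[0] == 8.0)
        assert field.flags[0] and field.flags[-1]

    def test_unordered_casts_rejected(self):
        casts = [cast([0, 10], [8, 8], DISSOLVED_OXYGEN, "2015-06-11"),
                 cast([0, 10], [4, 4], DISSOLVED_OXYGEN, "2015-06-01")]
        with pytest.raises(ValueError):
            ox.interpolate_temporal(casts)


class TestDailyMean:
    def _hourly(self, values_by_hour, start="2015-06-01"):
        times = pd.date_range(start, periods=len(values_by_hour), freq="h")
        vals = np.tile(np.asarray(values_by_hour, float), (3, 1))
        return ox.GriddedField(TEMPERATURE, np.array([0.0, 0.1, 0.2]), times, vals)

    def test_constant_day(self):
        daily = ox.daily_mean(self._hourly([7.0] * 24))
        assert daily.values[0, 0] == pytest.approx(7.0)
        assert not daily.flags[0]

    def test_split_day_mean(self):
        daily = ox.daily_mean(self._hourly([6.0] * 12 + [8.0] * 12))
        assert daily.values[0, 0] == pytest.approx(7.0)

    def test_partial_day_flagged(self):
        daily = ox.daily_mean(self._hourly([5.0, 6.0, 7.0]))
        assert daily.values[0, 0] == pytest.approx(6.0)
        assert daily.flags[0]


class TestIsoclineDepth:
    grid = np.round(np.arange(0, 10.1, 0.1), 6)

    def test_isotherm_inverse_linear(self):
        temps = 20.0 - self.grid  # 20 -> 10 over 0..10 m
        z = ox.isocline_depth(temps, self.grid, 14.0, "isotherm")
        assert z == pytest.approx(6.0, abs=1e-9)

    def test_isotherm_absent_when_column_cold(self):
        z = ox.isocline_depth(np.full(self.grid.size, 4.0), self.grid, 14.0, "isotherm")
        assert z == 0.0

    def test_oxycline_inverse_linear(self):
        do = 10.0 - self.grid  # 10 -> 0
        z = ox.isocline_depth(do, self.grid, 2.0, "oxycline")
        assert z == pytest.approx(8.0, abs=1e-9)

    def test_oxycline_absent_when_column_oxygenated(self):
        z = ox.isocline_depth(np.full(self.grid.size, 9.0), self.grid, 2.0, "oxycline")
        assert z > self.grid[-1]


class TestHabitatMask:
    grid = np.round(np.arange(0, 10.1, 0.1), 6)

    def test_whole_column_optimal(self):
        mask = ox.habitat_mask(np.full(101, 6.0), np.full(101, 8.0), tier="optimal")
        assert mask.all()

    def test_warm_surface_over_hypoxic_bottom_leaves_nothing(self):
        """Warm water to 5 m over hypoxia below 5 m: no usable habitat."""
        temps = np.where(self.grid <= 5.0, 15.0, 6.0)
        do = np.where(self.grid <= 5.0, 8.0, 1.0)
        mask = ox.habitat_mask(temps, do, tier="usable")
        assert not mask.any()

    def test_inversion_excludes_cool_water_above_warm_lens(self):
        temps = np.full(101, 9.0)
        temps[30] = 15.0  # single warm cell at 3.0 m
        mask = ox.habitat_mask(temps, np.full(101, 8.0), tier="usable")
        assert not mask[: 31].any()
        assert mask[31:].all()

    def test_mid_column_hypoxic_lens_excludes_only_itself(self):
        do = np.full(101, 8.0)
        do[40:45] = 1.0
        mask = ox.habitat_mask(np.full(101, 6.0), do, tier="usable")
        assert not mask[40:45].any()
        assert mask[:40].all() and mask[45:].all()

    def test_mask_matches_isoclines_on_monotone_profiles(self):
        temps = 22.0 - 1.5 * self.grid
        do = 10.0 - 0.9 * self.grid
        mask = ox.habitat_mask(temps, do, tier="usable")
        z_iso = ox.isocline_depth(temps, self.grid, 14.0, "isotherm")
        z_oxy = ox.isocline_depth(do, self.grid, 2.0, "oxycline")
        expect = (self.grid >= z_iso) & (self.grid < z_oxy)
        assert np.array_equal(mask, expect)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ox.habitat_mask(np.zeros(5), np.zeros(6))


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_optimal_mask_nested_in_usable(data):
    """For any profile pair, optimal habitat is a subset of usable habitat."""
    n = 61
    temps = np.array(data.draw(
        st.lists(st.floats(0.0, 30.0), min_size=n, max_size=n)))
    do = np.array(data.draw(
        st.lists(st.floats(0.0, 12.0), min_size=n, max_size=n)))
    optimal = ox.habitat_mask(temps, do, tier="optimal")
    usable = ox.habitat_mask(temps, do, tier="usable")
    assert not np.any(optimal & ~usable)


def test_interpolation_bounded_by_nodes():
    """Linear interpolation cannot overshoot its bracketing samples."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        depths = np.sort(rng.uniform(0, 13, size=6))
        depths[0] = 0.0
        values = rng.uniform(0, 25, size=6)
        col, _ = ox.interpolate_vertical(
            cast(depths, values), grid=np.arange(0, 13.01, 0.1))
        assert col.min() >= values.min() - 1e-12
        assert col.max() <= values.max() + 1e-12
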