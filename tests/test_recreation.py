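import numpy as np
import pytest

from corridorsim.errors import AllocationError, DataRangeError
from corridorsim.footprint_history import FootprintEvent, backcast
from corridorsim.grid_core import distance_to
from corridorsim.recreation import (
    ActivityRaster,
    ActivityScale,
    Trail,
    absolute_to_level,
    apply_scenario,
    backcast_activity,
    forecast_activity,
    level_to_absolute,
    rasterize_trails,
)

SCALE = ActivityScale(base=1.0, growth_factor=3.0)


class TestLevelScale:
    def test_forced_exponential_values(self):
        levels = np.array([0, 1, 2, 3, 4, 5])
        assert np.allclose(level_to_absolute(levels, SCALE), [0, 1, 3, 9, 27, 81])

    def test_roundtrip_exact_over_all_levels(self):
        levels = np.arange(6)
        assert np.array_equal(absolute_to_level(level_to_absolute(levels, SCALE), SCALE), levels)

    def test_categorical_change_slower_than_absolute(self):
        # 9 and 26.9 are nearly a factor 3 apart in absolute terms, same level
        assert absolute_to_level(np.array([9.0]), SCALE)[0] == 3
        assert absolute_to_level(np.array([26.9]), SCALE)[0] == 3

    def test_saturation_at_level_5(self):
        assert absolute_to_level(np.array([1e6]), SCALE)[0] == 5

    def test_sub_base_activity_clamps_to_level_1(self):
        assert absolute_to_level(np.array([0.01]), SCALE)[0] == 1

    def test_out_of_domain_rejected(self):
        with pytest.raises(DataRangeError):
            level_to_absolute(np.array([6]), SCALE)
        with pytest.raises(DataRangeError):
            absolute_to_level(np.array([-1.0]), SCALE)

    def test_doubling_absolute_subdoubles_mean_level(self, rng):
        a = rng.exponential(5.0, (30, 30))
        lvl = absolute_to_level(a, SCALE).astype(float)
        lvl2 = absolute_to_level(2 * a, SCALE).astype(float)
        assert lvl2.mean() < 2 * lvl.mean()
        assert (lvl2 >= lvl).all()  # monotone in absolute


class TestBackcastActivity:
    def test_activity_near_late_settlement_removed_and_remote_scaled(self, small_valley):
        cfg, state, activity, _ = small_valley
        grid = state.grid
        # append a settlement patch founded in 2005 far from others
        rows, cols = np.mgrid[2:4, 50:52]
        ev = FootprintEvent("settlement", 2005, rows.ravel(), cols.ravel(), np.ones(4))
        state2 = state.with_events(state.footprint_events + [ev])
        act = activity.copy()
        mask = np.zeros(grid.shape, dtype=bool)
        mask[ev.rows, ev.cols] = True
        d = distance_to(mask, grid)
        near = (d > 1000) & (d < 2000)
        r, c = np.argwhere(near)[0]
        act.absolute[r, c] = 5.0  # activity 1-2 km from the 2005 settlement
        past_state = backcast(state2, 2000)
        past = backcast_activity(act, state2, past_state, pop_growth=0.5, scale=SCALE)
        assert past.absolute[r, c] == 0.0

    def test_no_late_footprint_and_zero_growth_is_identity(self, small_valley):
        cfg, state, activity, _ = small_valley
        past_state = backcast(state, state.year)
        past = backcast_activity(activity, state, past_state, 0.0, SCALE)
        assert np.allclose(past.absolute, activity.absolute)

    def test_total_matches_population_trajectory(self, small_valley):
        cfg, state, activity, _ = small_valley
        for year, growth in ((2010, 0.3), (1990, 1.2)):
            past_state = backcast(state, year)
            past = backcast_activity(activity, state, past_state, growth, SCALE)
            assert past.absolute.sum() * (1 + growth) == pytest.approx(
                activity.absolute.sum(), rel=1e-3
            )


def _flat_activity(state, value=4.0):
    """Uniform activity on a simple diagonal trail through the canmore zone."""
    grid = state.grid
    cs = grid.cell_size
    coords = np.array([[5 * cs, 5 * cs], [30 * cs, 30 * cs]])
    trail = Trail(coords, designated=True)
    absolute = np.zeros(grid.shape)
    absolute[rasterize_trails([trail], grid)] = value
    return ActivityRaster(grid, absolute, absolute_to_level(absolute, SCALE), [trail])


class TestForecastActivity:
    def test_zone_mass_balance(self, small_valley):
        cfg, state, activity, _ = small_valley
        g = 0.25
        pre = activity.absolute[state.zone("canmore")].sum()
        new_settlement = np.zeros(state.grid.shape, dtype=bool)
        out = forecast_activity(activity, state, new_settlement, {"canmore": g}, SCALE, rng_seed=1)
        post = out.absolute[state.zone("canmore")].sum()
        assert post == pytest.approx((1 + g) * pre, rel=1e-3)

    def test_mass_balance_with_new_trails(self, small_valley):
        cfg, state, activity, _ = small_valley
        zone = state.zone("canmore")
        # pretend a block inside the zone was newly settled this decade
        new_settlement = np.zeros(state.grid.shape, dtype=bool)
        rs, cs_ = np.argwhere(zone)[len(np.argwhere(zone)) // 2]
        new_settlement[rs : rs + 2, cs_ : cs_ + 2] = True
        g = 0.3
        pre = activity.absolute[zone].sum()
        out = forecast_activity(activity, state, new_settlement, {"canmore": g}, SCALE, rng_seed=2)
        assert out.absolute[zone].sum() == pytest.approx((1 + g) * pre, rel=1e-3)

    def test_banff_trails_intensify_25_percent_per_decade(self, small_valley):
        cfg, state, activity, _ = small_valley
        banff = state.zone("banff")
        trail_cells = activity.trail_mask() & banff
        assert trail_cells.any()
        out = forecast_activity(activity, state, np.zeros(state.grid.shape, bool), {}, SCALE, rng_seed=0)
        assert np.allclose(out.absolute[trail_cells], activity.absolute[trail_cells] * 1.25)

    def test_zero_growth_leaves_non_banff_unchanged(self, small_valley):
        cfg, state, activity, _ = small_valley
        out = forecast_activity(activity, state, np.zeros(state.grid.shape, bool), {"canmore": 0.0}, SCALE, rng_seed=0)
        outside_banff = ~state.zone("banff")
        assert np.array_equal(out.absolute[outside_banff], activity.absolute[outside_banff])

    def test_no_trails_in_growing_zone_raises(self, small_valley):
        cfg, state, activity, _ = small_valley
        bare = ActivityRaster(state.grid, activity.absolute.copy(), activity.level.copy(), [])
        bare.absolute[:] = 1.0  # activity exists but no trail network
        with pytest.raises(AllocationError):
            forecast_activity(bare, state, np.zeros(state.grid.shape, bool), {"canmore": 0.5}, SCALE)


class TestApplyScenario:
    def test_base_is_identity(self, small_valley):
        _, state, activity, _ = small_valley
        out = apply_scenario(activity, state, "base", SCALE)
        assert np.array_equal(out.absolute, activity.absolute)

    def test_restricted_recreation_distance_rule(self, small_valley):
        _, state, activity, _ = small_valley
        d = distance_to(state.settlement_mask(), state.grid)
        act = activity.copy()
        act.absolute[:] = 10.0
        act.level = absolute_to_level(act.absolute, SCALE)
        out = apply_scenario(act, state, "restricted_recreation", SCALE)
        assert np.allclose(out.absolute[d < 100.0], 10.0)  # within 100 m: unchanged
        assert np.allclose(out.absolute[d >= 100.0], 5.0)  # beyond: halved

    def test_no_informal_trails_rule(self, small_valley):
        _, state, activity, _ = small_valley
        out = apply_scenario(activity, state, "no_informal_trails", SCALE)
        designated = activity.trail_mask(designated_only=True)
        informal_only = activity.trail_mask() & ~designated & (
            state.stack.anthropogenic_fraction() == 0
        )
        assert informal_only.any()
        assert (out.absolute[informal_only] == 0).all()
        assert np.array_equal(out.absolute[designated], activity.absolute[designated])

    def test_every_scenario_dominated_by_base(self, small_valley):
        _, state, activity, _ = small_valley
        for scenario in ("no_informal_trails", "restricted_recreation", "limited_urban_expansion"):
            out = apply_scenario(activity, state, scenario, SCALE)
            assert (out.absolute <= activity.absolute + 1e-12).all()

    def test_unknown_scenario_rejected(self, small_valley):
        _, state, activity, _ = small_valley
        with pytest.raises(ValueError):
            apply_scenario(activity, state, "build_more_condos", SCALE)
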