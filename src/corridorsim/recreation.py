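"""Recreation activity model: level scale, history, forecast and scenarios.

Recreation intensity is carried in two co-registered rasters: an *absolute*
activity raster (arbitrary units, e.g. passes per season) and a heatmap-style
*level* raster in {0..5}. The two are linked by an exponential scale —
absolute activity at level k is A0 * g**(k-1) — so categorical levels change
more slowly than the underlying absolute activity, mirroring how heatmap
colour classes respond to traffic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AllocationError, DataRangeError
from .footprint_history import LandscapeState
from .grid_core import Grid, distance_to

SCENARIOS = ("base", "limited_urban_expansion", "no_informal_trails", "restricted_recreation")

MAX_LEVEL = 5


@dataclass(frozen=True)
class Trail:
    """A trail polyline in grid metres; informal trails are non-designated."""

    coords: np.ndarray  # (n, 2) array of (x, y)
    designated: bool

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 2))


@dataclass(frozen=True)
class ActivityScale:
    """Exponential level-to-activity relation: A(k) = A0 * g**(k-1), A(0) = 0."""

    base: float = 1.0  # A0, absolute activity at level 1
    growth_factor: float = 3.0  # g, ratio between consecutive levels

    def __post_init__(self):
        if self.base <= 0 or self.growth_factor <= 1:
            raise ValueError("require base > 0 and growth_factor > 1")


@dataclass
class ActivityRaster:
    """Paired absolute-activity and 0-5 level rasters plus the trail network."""

    grid: Grid
    absolute: np.ndarray
    level: np.ndarray
    trails: list[Trail] = field(default_factory=list)

    def __post_init__(self):
        self.grid.check(self.absolute)
        self.grid.check(self.level)

    def copy(self) -> "ActivityRaster":
        return ActivityRaster(self.grid, self.absolute.copy(), self.level.copy(), list(self.trails))

    def trail_mask(self, designated_only: bool = False) -> np.ndarray:
        trails = [t for t in self.trails if t.designated] if designated_only else self.trails
        return rasterize_trails(trails, self.grid)

    def total(self, mask: np.ndarray | None = None) -> float:
        if mask is None:
            return float(self.absolute.sum())
        return float(self.absolute[mask].sum())

    def validate(self) -> None:
        if ((self.level == 0) != (self.absolute == 0)).any():
            raise DataRangeError("level 0 must coincide exactly with zero absolute activity")


def rasterize_trails(trails: list[Trail], grid: Grid) -> np.ndarray:
    """Boolean mask of cells any trail polyline passes through."""
    mask = np.zeros(grid.shape, dtype=bool)
    for trail in trails:
        xy = trail.coords
        for k in range(len(xy) - 1):
            p, q = xy[k], xy[k + 1]
            seg_len = float(np.hypot(*(q - p)))
            n = max(2, int(np.ceil(seg_len / (grid.cell_size / 2))) + 1)
            t = np.linspace(0.0, 1.0, n)
            pts = p[None, :] * (1 - t)[:, None] + q[None, :] * t[:, None]
            cols = np.clip(((pts[:, 0] - grid.origin[0]) // grid.cell_size).astype(int), 0, grid.n_cols - 1)
            rows = np.clip(((pts[:, 1] - grid.origin[1]) // grid.cell_size).astype(int), 0, grid.n_rows - 1)
            mask[rows, cols] = True
    return mask


def level_to_absolute(level: np.ndarray, scale: ActivityScale) -> np.ndarray:
    """Elementwise absolute activity for each 0-5 level."""
    level = np.asarray(level)
    if ((level < 0) | (level > MAX_LEVEL)).any():
        raise DataRangeError("activity levels must lie in {0..5}")
    out = scale.base * np.power(float(scale.growth_factor), level.astype(float) - 1.0)
    return np.where(level == 0, 0.0, out)


def absolute_to_level(absolute: np.ndarray, scale: ActivityScale) -> np.ndarray:
    """Elementwise 0-5 level for absolute activity (floor-log binning, clamped)."""
    absolute = np.asarray(absolute, dtype=float)
    if (absolute < 0).any():
        raise DataRangeError("absolute activity must be non-negative")
    with np.errstate(divide="ignore"):
        k = 1 + np.floor(np.log(absolute / scale.base) / np.log(scale.growth_factor))
    k = np.clip(k, 1, MAX_LEVEL)
    return np.where(absolute == 0, 0, k).astype(np.int8)


def _with_absolute(activity: ActivityRaster, absolute: np.ndarray, scale: ActivityScale) -> ActivityRaster:
    return ActivityRaster(activity.grid, absolute, absolute_to_level(absolute, scale), list(activity.trails))


def backcast_activity(
    current: ActivityRaster,
    current_landscape: LandscapeState,
    landscape_t: LandscapeState,
    pop_growth: float,
    scale: ActivityScale,
) -> ActivityRaster:
    """Reconstruct activity at the backcast year of ``landscape_t``.

    Activity inside recreation facilities, or within 2 km of settlement
    patches, is assumed generated by that footprint and is removed wherever
    the footprint postdates the target year. Remaining activity is rescaled
    by one factor so that regional growth from then to now matches the
    population growth rate (``pop_growth`` is the fractional growth from the
    target year to the present).
    """
    grid = current.grid
    target_year = landscape_t.year
    removed = np.zeros(grid.shape, dtype=bool)
    for ev in current_landscape.footprint_events:
        if ev.origin_year <= target_year:
            continue
        if ev.class_name == "recreation_facility":
            removed[ev.rows, ev.cols] = True
        elif ev.class_name == "settlement":
            mask = np.zeros(grid.shape, dtype=bool)
            mask[ev.rows, ev.cols] = True
            removed |= distance_to(mask, grid) <= 2000.0
    absolute = np.where(removed, 0.0, current.absolute)
    remaining = float(absolute.sum())
    target_total = current.total() / (1.0 + pop_growth)
    if remaining > 0:
        absolute = absolute * (target_total / remaining)
    elif target_total > 0:
        warnings.warn("all activity removed by footprint rules; backcast total is zero")
    return _with_absolute(current, absolute, scale)


def _new_trails_near(
    new_settlement: np.ndarray,
    grid: Grid,
    rng: np.random.Generator,
    n_trails: int = 6,
    max_steps: int = 25,
) -> list[Trail]:
    """Random-walk trail polylines seeded at new settlement edge cells.

    Walks are persistent (correlated headings) and stay within 2 km of the
    new settlement cells.
    """
    trails: list[Trail] = []
    if not new_settlement.any():
        return trails
    dist = distance_to(new_settlement, grid)
    edge_idx = np.flatnonzero(new_settlement)
    cs = grid.cell_size
    for _ in range(n_trails):
        start = np.unravel_index(rng.choice(edge_idx), grid.shape)
        r, c = float(start[0]), float(start[1])
        heading = rng.uniform(0, 2 * np.pi)
        pts = [(grid.origin[0] + (c + 0.5) * cs, grid.origin[1] + (r + 0.5) * cs)]
        for _ in range(int(rng.integers(max_steps // 2, max_steps + 1))):
            heading += rng.normal(0, 0.5)
            r2 = r + np.sin(heading)
            c2 = c + np.cos(heading)
            ri, ci = int(round(r2)), int(round(c2))
            if not (0 <= ri < grid.n_rows and 0 <= ci < grid.n_cols):
                break
            if dist[ri, ci] > 2000.0:
                break
            r, c = r2, c2
            pts.append((grid.origin[0] + (c + 0.5) * cs, grid.origin[1] + (r + 0.5) * cs))
        if len(pts) >= 2:
            trails.append(Trail(np.asarray(pts), designated=False))
    return trails


def forecast_activity(
    current: ActivityRaster,
    landscape: LandscapeState,
    new_settlement_mask: np.ndarray,
    growth: dict[str, float],
    scale: ActivityScale,
    rng_seed: int | np.random.Generator = 0,
    decades: int = 1,
    banff_trail_growth_per_decade: float = 0.25,
) -> ActivityRaster:
    """Grow recreation activity alongside settlement expansion.

    For each municipality zone named in ``growth``, total new absolute
    activity equals the growth fraction times the zone's current total; half
    intensifies existing trail cells (proportionally to their current use)
    and half is placed on new informal trails generated within 2 km of new
    settlement cells. The Banff zone instead intensifies existing trails by
    a fixed fraction per decade, with no new trails.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    grid = current.grid
    absolute = current.absolute.astype(float).copy()
    trails = list(current.trails)
    trail_cells = current.trail_mask()

    for zone_name, frac in growth.items():
        if frac < 0:
            raise ValueError("growth fractions must be non-negative")
        if frac == 0:
            continue
        zone = landscape.zone(zone_name)
        zone_total = float(current.absolute[zone].sum())
        if zone_total == 0:
            continue
        new_total = frac * zone_total
        on_trails = trail_cells & zone & (current.absolute > 0)
        if not on_trails.any():
            raise AllocationError(zone_name, f"no active trail cells to intensify in zone {zone_name!r}")
        zone_new_settlement = new_settlement_mask & zone
        half = 0.5 * new_total
        intensify = half if zone_new_settlement.any() else new_total
        absolute[on_trails] += intensify * current.absolute[on_trails] / current.absolute[on_trails].sum()
        if zone_new_settlement.any():
            fresh = _new_trails_near(zone_new_settlement, grid, rng)
            # keep the new-trail mass inside the municipality so zone totals balance
            fresh_mask = rasterize_trails(fresh, grid) & ~trail_cells & zone
            if not fresh_mask.any():
                absolute[on_trails] += half * current.absolute[on_trails] / current.absolute[on_trails].sum()
            else:
                absolute[fresh_mask] += half / fresh_mask.sum()
                trails.extend(fresh)

    banff = landscape.zone("banff")
    if banff.any():
        banff_trails = trail_cells & banff
        absolute[banff_trails] *= (1.0 + banff_trail_growth_per_decade) ** decades

    out = ActivityRaster(grid, absolute, absolute_to_level(absolute, scale), trails)
    return out


def apply_scenario(
    activity: ActivityRaster,
    landscape: LandscapeState,
    scenario: str,
    scale: ActivityScale,
) -> ActivityRaster:
    """Apply a mitigation scenario's map-level activity rule.

    ``base`` is the identity. ``no_informal_trails`` removes activity
    everywhere off designated trails and off development footprint.
    ``restricted_recreation`` halves activity at least 100 m from settlement.
    ``limited_urban_expansion`` acts through pre-scaled growth inputs during
    the forecast, so it is also a map-level identity here.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario in ("base", "limited_urban_expansion"):
        return activity.copy()
    if scenario == "no_informal_trails":
        keep = activity.trail_mask(designated_only=True) | (landscape.stack.anthropogenic_fraction() > 0)
        absolute = np.where(keep, activity.absolute, 0.0)
        return _with_absolute(activity, absolute, scale)
    # restricted_recreation
    dist = distance_to(landscape.settlement_mask(), activity.grid)
    absolute = np.where(dist >= 100.0, activity.absolute * 0.5, activity.absolute)
    return _with_absolute(activity, absolute, scale)
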