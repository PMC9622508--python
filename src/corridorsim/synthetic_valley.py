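"""Synthetic mountain-valley landscape generator.

Builds a Bow-Valley-like study system with the statistical structure the
analysis assumes, so the whole pipeline is testable without proprietary
GIS, heatmap or collar inputs: a low-elevation valley flanked by steep
slopes, development footprint concentrated on the valley floor, a fenced
highway with sparse dated wildlife crossings, recreation activity strongly
clustered within 2 km of settlements, and collar locations concentrated in
preferred (high-permeability) habitat.

Everything is driven by one seeded generator, so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError
from .footprint_history import Crossing, FootprintEvent, LandscapeState
from .grid_core import Grid, distance_to
from .recreation import ActivityRaster, ActivityScale, Trail, absolute_to_level, rasterize_trails


@dataclass
class SettlementSeed:
    """A town or hamlet: centre (fractions of grid extent), size and history."""

    name: str
    col_frac: float
    row_offset_cells: int  # rows north (-) or south (+) of the valley centre
    core_radius_cells: int
    founding_year: int
    # (origin year, ring width in cells) growth rings applied outward from the core
    growth_rings: tuple[tuple[int, int], ...] = ()


@dataclass
class ValleyConfig:
    """Parameters of the synthetic valley (defaults give a ~900 km² study area)."""

    n_rows: int = 200
    n_cols: int = 450
    cell_size: float = 100.0
    current_year: int = 2020

    # terrain
    floor_elevation_m: float = 1300.0
    relief_m: float = 1200.0
    noise_amplitude_m: float = 40.0
    noise_smoothness_cells: float = 6.0

    # highway & crossings: (fraction along the valley axis, construction year)
    highway_row_offset_cells: int = 8
    crossing_specs: tuple[tuple[float, int], ...] = (
        (0.12, 1988),
        (0.32, 1997),
        (0.52, 2005),
        (0.72, 2013),
        (0.90, 2030),  # planned
    )

    settlements: tuple[SettlementSeed, ...] = (
        SettlementSeed("banff", 0.22, -10, 10, 1890, ((1975, 1), (1995, 1))),
        SettlementSeed("canmore", 0.70, -8, 7, 1895, ((1975, 2), (1990, 2), (2005, 2), (2015, 1))),
        SettlementSeed("hamlet_west", 0.42, -6, 3, 1950, ((2000, 1),)),
        SettlementSeed("hamlet_east", 0.86, -7, 3, 1960, ((1995, 1),)),
        SettlementSeed("hamlet_south", 0.60, 14, 3, 1955, ()),
    )

    # trails / recreation
    trails_per_settlement: int = 14  # for a core-radius-7 settlement; scales with size
    trail_max_steps: int = 40
    informal_trail_fraction: float = 0.4
    activity_decay_m: float = 900.0
    activity_base: float = 1.0
    activity_growth_factor: float = 3.0

    # collar sampling
    n_collar_cells: int = 400
    n_animals: int = 30

    rng_seed: int = 7

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, self.cell_size)

    @property
    def scale(self) -> ActivityScale:
        return ActivityScale(self.activity_base, self.activity_growth_factor)

    @property
    def size_factor(self) -> float:
        """Linear scaling of patch radii relative to the default 200x450 grid."""
        return float(np.sqrt((self.n_rows * self.n_cols) / (200.0 * 450.0)))


def _disk(shape: tuple[int, int], centre: tuple[int, int], radius: float) -> np.ndarray:
    i, j = np.ogrid[0 : shape[0], 0 : shape[1]]
    return (i - centre[0]) ** 2 + (j - centre[1]) ** 2 <= radius**2


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Zero-mean unit-ish smooth random field."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _elevation(cfg: ValleyConfig, rng: np.random.Generator) -> np.ndarray:
    """Parabolic U-shaped valley cross-section plus low-amplitude smooth noise."""
    rows = np.arange(cfg.n_rows, dtype=float)
    centre = (cfg.n_rows - 1) / 2.0
    half = cfg.n_rows / 2.0
    cross = cfg.floor_elevation_m + cfg.relief_m * ((rows - centre) / half) ** 2
    noise = _smooth_noise(rng, (cfg.n_rows, cfg.n_cols), cfg.noise_smoothness_cells)
    return cross[:, None] + cfg.noise_amplitude_m * noise


def _natural_cover(cfg: ValleyConfig, elevation: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Potential natural cover fractions assigned by elevation band.

    Soft logistic transitions between forest (low), shrub (mid) and alpine
    (high); a meandering river strip along the valley axis is water.
    """

    def logistic(z: np.ndarray, z0: float, width: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(z - z0) / width))

    shrub_on = logistic(elevation, 1750.0, 60.0)
    alpine_on = logistic(elevation, 2050.0, 60.0)
    forest = 1.0 - shrub_on
    shrub = shrub_on * (1.0 - alpine_on)
    alpine = shrub_on * alpine_on

    water = np.zeros((cfg.n_rows, cfg.n_cols))
    centre = (cfg.n_rows - 1) // 2
    meander = _smooth_noise(rng, (1, cfg.n_cols), 12.0)[0]
    river_rows = np.clip(centre + np.round(4.0 * meander).astype(int), 0, cfg.n_rows - 1)
    water[river_rows, np.arange(cfg.n_cols)] = 1.0

    remainder = 1.0 - water
    return {
        "forest": forest * remainder,
        "shrub": shrub * remainder,
        "alpine": alpine * remainder,
        "water": water,
    }


def _event_from_mask(
    mask: np.ndarray, class_name: str, year: int, fraction: float, claimed: np.ndarray
) -> FootprintEvent | None:
    """Turn a patch mask into a dated event, respecting already-claimed capacity."""
    free = np.maximum(1.0 - claimed, 0.0)
    take = np.where(mask, np.minimum(fraction, free), 0.0)
    rows, cols = np.nonzero(take > 1e-12)
    if rows.size == 0:
        return None
    fr = take[rows, cols]
    claimed[rows, cols] += fr
    return FootprintEvent(class_name, year, rows, cols, fr)


def _random_walk_trail(
    rng: np.random.Generator,
    grid: Grid,
    start_rc: tuple[int, int],
    max_steps: int,
    designated: bool,
) -> Trail:
    r, c = float(start_rc[0]), float(start_rc[1])
    heading = rng.uniform(0, 2 * np.pi)
    cs = grid.cell_size
    pts = [(grid.origin[0] + (c + 0.5) * cs, grid.origin[1] + (r + 0.5) * cs)]
    for _ in range(int(rng.integers(max_steps // 2, max_steps + 1))):
        heading += rng.normal(0, 0.45)
        r2, c2 = r + np.sin(heading), c + np.cos(heading)
        if not (0 <= r2 < grid.n_rows and 0 <= c2 < grid.n_cols):
            break
        r, c = r2, c2
        pts.append((grid.origin[0] + (c + 0.5) * cs, grid.origin[1] + (r + 0.5) * cs))
    return Trail(np.asarray(pts), designated=designated)


def generate_landscape(cfg: ValleyConfig) -> tuple[LandscapeState, ActivityRaster, pd.DataFrame]:
    """Generate the full synthetic study system for the configured seed.

    Returns the current-year landscape state, the current activity raster
    and a collar-location table. Raises :class:`GenerationError` if the
    generated activity violates the settlement-proximity structure the
    analysis assumes (>80% of absolute activity within 2 km of settlement).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    grid = cfg.grid
    shape = grid.shape
    sf = cfg.size_factor

    elevation = _elevation(cfg, rng)
    pnv = _natural_cover(cfg, elevation, rng)

    centre_row = (cfg.n_rows - 1) // 2
    claimed = np.zeros(shape)
    events: list[FootprintEvent] = []

    def add_event(mask: np.ndarray, class_name: str, year: int, fraction: float) -> None:
        ev = _event_from_mask(mask, class_name, year, fraction, claimed)
        if ev is not None:
            events.append(ev)

    # --- linear features along the valley floor -------------------------------
    highway_row = min(cfg.n_rows - 1, centre_row + cfg.highway_row_offset_cells)
    highway_mask = np.zeros(shape, dtype=bool)
    highway_mask[highway_row, :] = True
    add_event(highway_mask, "linear", 1955, 0.5)
    railway = np.zeros(shape, dtype=bool)
    railway[max(0, centre_row - 4), :] = True
    add_event(railway, "linear", 1920, 0.3)

    # --- settlements with dated growth rings ----------------------------------
    settlement_centres: dict[str, tuple[int, int]] = {}
    for seed in cfg.settlements:
        rc = (centre_row + seed.row_offset_cells, int(seed.col_frac * (cfg.n_cols - 1)))
        settlement_centres[seed.name] = rc
        radius = seed.core_radius_cells * sf
        core = _disk(shape, rc, radius)
        add_event(core, "settlement", min(seed.founding_year, 1950), 1.0)
        prev = core
        for year, width in seed.growth_rings:
            radius += width * sf
            ring = _disk(shape, rc, radius) & ~prev
            add_event(ring, "settlement", year, 1.0)
            prev = prev | ring
        # access roads hugging the settlement
        road_ring = _disk(shape, rc, radius + 2 * sf) & ~prev
        add_event(road_ring & (rng.random(shape) < 0.25), "linear", seed.founding_year, 0.4)

    # --- recreation facilities, industry, farmland ----------------------------
    banff_rc = settlement_centres["banff"]
    canmore_rc = settlement_centres["canmore"]
    ski = _disk(shape, (max(0, banff_rc[0] - int(35 * sf)), banff_rc[1] - int(20 * sf)), 17 * sf)
    add_event(ski, "recreation_facility", 1965, 1.0)
    golf = _disk(shape, (banff_rc[0] + int(14 * sf), banff_rc[1] + int(12 * sf)), 8 * sf)
    add_event(golf, "recreation_facility", 1960, 1.0)
    nordic_rc = (max(0, canmore_rc[0] - int(14 * sf)), canmore_rc[1] - int(10 * sf))
    nordic = _disk(shape, nordic_rc, 7 * sf)
    add_event(nordic, "recreation_facility", 1987, 1.0)
    quarry1 = _disk(shape, (centre_row + int(16 * sf), canmore_rc[1] + int(28 * sf)), 11 * sf)
    add_event(quarry1, "industrial", 1975, 1.0)
    quarry2 = _disk(shape, (centre_row - int(18 * sf), int(0.5 * cfg.n_cols)), 8 * sf)
    add_event(quarry2, "industrial", 1998, 1.0)
    farm = _disk(shape, (centre_row + int(10 * sf), int(0.96 * cfg.n_cols)), 3.5 * sf)
    add_event(farm, "farmland", 1940, 1.0)

    # --- crossings -------------------------------------------------------------
    crossings = [
        Crossing(highway_row, int(frac * (cfg.n_cols - 1)), year) for frac, year in cfg.crossing_specs
    ]

    # --- planning zones --------------------------------------------------------
    def zone_disk(rc: tuple[int, int], radius_m: float) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[rc] = True
        return distance_to(m, grid) <= radius_m * sf

    banff_zone = zone_disk(banff_rc, 3000.0)
    canmore_core_zone = zone_disk(canmore_rc, 4000.0) & ~banff_zone
    atbd = np.zeros(shape, dtype=bool)
    atbd[
        max(0, canmore_rc[0] - int(10 * sf)) : centre_row + int(6 * sf),
        canmore_rc[1] + int(10 * sf) : min(cfg.n_cols, canmore_rc[1] + int(34 * sf)),
    ] = True
    atbd &= ~canmore_core_zone & ~banff_zone
    canmore_settlement_now = np.zeros(shape, dtype=bool)
    for ev in events:
        if ev.class_name == "settlement":
            canmore_settlement_now[ev.rows, ev.cols] = True
    growth_boundary = (
        (distance_to(canmore_settlement_now & canmore_core_zone, grid) <= 1200.0 * sf)
        & ~canmore_settlement_now
        & canmore_core_zone
    )
    canmore_zone = canmore_core_zone | atbd
    zones = {
        "banff": banff_zone,
        "canmore": canmore_zone,
        "town_center": zone_disk(canmore_rc, 300.0),
        "growth_boundary": growth_boundary,
        "area_to_be_determined": atbd,
        "nordic_centre": zone_disk(nordic_rc, 1500.0),
        "rural": ~(banff_zone | canmore_zone),
    }

    state = LandscapeState(
        grid=grid,
        year=cfg.current_year,
        pnv=pnv,
        elevation=elevation,
        footprint_events=events,
        crossings=crossings,
        zones=zones,
        highway_mask=highway_mask,
        highway_built_year=1955,
    )
    state.stack.validate()

    activity = _generate_activity(cfg, state, rng)
    collar = _generate_collar(cfg, state, rng)
    return state, activity, collar


def _generate_activity(cfg: ValleyConfig, state: LandscapeState, rng: np.random.Generator) -> ActivityRaster:
    grid = state.grid
    settlement = state.settlement_mask()
    d_settlement = distance_to(settlement, grid)

    trails: list[Trail] = []
    dilated_edge = ndimage.binary_dilation(settlement) & ~settlement
    centre_row = (cfg.n_rows - 1) // 2
    for seed in cfg.settlements:
        rc = (centre_row + seed.row_offset_cells, int(seed.col_frac * (cfg.n_cols - 1)))
        near = np.zeros(grid.shape, dtype=bool)
        near[rc] = True
        local_edge = np.argwhere(dilated_edge & (distance_to(near, grid) <= 3000.0 * cfg.size_factor))
        if len(local_edge) == 0:
            continue
        n_trails = max(4, int(round(cfg.trails_per_settlement * seed.core_radius_cells / 7.0)))
        for _ in range(n_trails):
            start = tuple(local_edge[rng.integers(len(local_edge))])
            designated = rng.random() >= cfg.informal_trail_fraction
            trails.append(_random_walk_trail(rng, grid, start, cfg.trail_max_steps, designated))

    g = cfg.activity_growth_factor
    absolute = np.zeros(grid.shape)
    trail_cells = rasterize_trails(trails, grid)
    # trail use decays with distance from settlement (heatmap-like hot cores)
    u = 4.0 * np.exp(-d_settlement / cfg.activity_decay_m) + rng.normal(0, 0.3, grid.shape)
    absolute[trail_cells] = cfg.activity_base * g ** np.clip(u[trail_cells], 0.0, 4.2)
    # in-town and roadside recorded activity
    footprint = state.stack.anthropogenic_fraction() > 0.2
    u_town = 3.0 * np.exp(-d_settlement / (2 * cfg.activity_decay_m))
    absolute[footprint] = np.maximum(
        absolute[footprint], cfg.activity_base * g ** np.clip(u_town[footprint], 0.0, 4.0)
    )
    rec = state.stack.fraction("recreation_facility") > 0
    absolute[rec] = np.maximum(absolute[rec], cfg.activity_base * g**2.0)

    within = d_settlement <= 2000.0
    frac_near = absolute[within].sum() / absolute.sum()
    if frac_near <= 0.80:
        raise GenerationError(
            f"only {100 * frac_near:.1f}% of activity lies within 2 km of settlement "
            "(need > 80%); increase activity_decay concentration or settlement extent"
        )
    level = absolute_to_level(absolute, cfg.scale)
    return ActivityRaster(grid, absolute, level, trails)


def _generate_collar(cfg: ValleyConfig, state: LandscapeState, rng: np.random.Generator) -> pd.DataFrame:
    """Collar points sampled preferentially from high-permeability natural cells."""
    from .connectivity import PermeabilityModel, permeability

    grid = state.grid
    perm = permeability(state, PermeabilityModel.synthetic_default())
    natural = (state.stack.anthropogenic_fraction() == 0) & (
        state.highway_mask is None or ~state.highway_mask
    )
    weights = np.where(natural, perm**2, 0.0).ravel()
    if weights.sum() == 0:
        raise GenerationError("no natural cells available for collar sampling")
    weights /= weights.sum()
    n_cells = min(cfg.n_collar_cells, int((weights > 0).sum()))
    cells = rng.choice(grid.n_rows * grid.n_cols, size=n_cells, replace=False, p=weights)

    rows_out = []
    base_ts = pd.Timestamp("2018-05-01")
    for cell in cells:
        r, c = divmod(int(cell), grid.n_cols)
        n_pts = 2 + int(rng.poisson(1.0))
        for _ in range(n_pts):
            x = grid.origin[0] + (c + rng.random()) * grid.cell_size
            y = grid.origin[1] + (r + rng.random()) * grid.cell_size
            rows_out.append(
                {
                    "x": x,
                    "y": y,
                    "animal_id": int(rng.integers(1, cfg.n_animals + 1)),
                    "timestamp": base_ts + pd.Timedelta(hours=float(rng.integers(0, 2 * 365 * 24))),
                }
            )
    return pd.DataFrame(rows_out)


def toy_landscape(n: int = 5) -> LandscapeState:
    """Deterministic n x n fixture: one highway row with one crossing, one
    settlement patch, forest elsewhere. Used by exact oracle tests."""
    if n > 20:
        raise ValueError("toy landscapes are capped at 20 x 20")
    grid = Grid(n, n, 100.0)
    rows = np.arange(n, dtype=float)
    elevation = 1300.0 + 400.0 * ((rows - (n - 1) / 2) / max(n / 2, 1)) ** 2
    elevation = np.repeat(elevation[:, None], n, axis=1)
    pnv = {"forest": np.ones((n, n))}
    highway_row = n // 2
    highway_mask = np.zeros((n, n), dtype=bool)
    highway_mask[highway_row, :] = True
    events = [
        FootprintEvent("linear", 1950, np.full(n, highway_row), np.arange(n), np.full(n, 0.5)),
        FootprintEvent(
            "settlement",
            1980,
            np.array([0, 0, 1, 1]),
            np.array([0, 1, 0, 1]),
            np.ones(4),
        ),
    ]
    crossings = [Crossing(highway_row, n // 2, 1985)]
    return LandscapeState(
        grid=grid,
        year=2020,
        pnv=pnv,
        elevation=elevation,
        footprint_events=events,
        crossings=crossings,
        zones={"rural": np.ones((n, n), dtype=bool)},
        highway_mask=highway_mask,
        highway_built_year=1950,
    )
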