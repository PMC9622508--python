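"""Dated development-footprint history: backcasting and forecast growth.

A :class:`LandscapeState` stores the landscape as (a) a potential-natural
cover composition per cell and (b) a list of dated footprint events
(patch, class, origin year). The visible cover stack at any year is a pure
function of those two, so removing events (backcasting) and re-applying
them round-trips bit-identically.

Forecast growth follows simple allocation rules: settlement expands
outward from existing patches, with new cells drawn preferentially next to
larger patches (patch-size-biased weights), staged through named planning
zones where those exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import AllocationError
from .grid_core import NATURAL_CLASSES, CoverStack, Grid, distance_to

_STRUCTURE8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FootprintEvent:
    """A dated footprint patch: cells, cover class and per-cell fraction added."""

    class_name: str
    origin_year: int
    rows: np.ndarray
    cols: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=np.intp))
        object.__setattr__(self, "cols", np.asarray(self.cols, dtype=np.intp))
        object.__setattr__(
            self, "fractions", np.broadcast_to(np.asarray(self.fractions, dtype=float), self.rows.shape).copy()
        )

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)


@dataclass(frozen=True)
class Crossing:
    """A wildlife crossing structure on the highway, with its construction year."""

    row: int
    col: int
    year_built: int


@dataclass
class LandscapeState:
    """The simulated world at one time step.

    ``pnv`` (potential natural vegetation) gives the natural cover
    composition each cell reverts to when footprint is removed; the visible
    stack is composed from ``pnv`` plus all events dated at or before
    ``year``.
    """

    grid: Grid
    year: int
    pnv: dict[str, np.ndarray]
    elevation: np.ndarray
    footprint_events: list[FootprintEvent] = field(default_factory=list)
    crossings: list[Crossing] = field(default_factory=list)
    zones: dict[str, np.ndarray] = field(default_factory=dict)
    highway_mask: np.ndarray | None = None
    highway_built_year: int = 1955

    def __post_init__(self):
        self.footprint_events = sorted(self.footprint_events, key=lambda e: e.origin_year)
        self._stack: CoverStack | None = None

    @property
    def stack(self) -> CoverStack:
        if self._stack is None:
            self._stack = compose_stack(self.grid, self.pnv, self.active_events())
        return self._stack

    def active_events(self) -> list[FootprintEvent]:
        return [e for e in self.footprint_events if e.origin_year <= self.year]

    def open_crossings(self) -> list[Crossing]:
        return [c for c in self.crossings if c.year_built <= self.year]

    def zone(self, name: str) -> np.ndarray:
        if name not in self.zones:
            return np.zeros(self.grid.shape, dtype=bool)
        return self.zones[name]

    def settlement_mask(self) -> np.ndarray:
        return self.stack.fraction("settlement") > 0

    def with_events(self, events: list[FootprintEvent], year: int | None = None) -> "LandscapeState":
        return replace(
            self,
            year=self.year if year is None else year,
            footprint_events=list(events),
        )


def compose_stack(grid: Grid, pnv: dict[str, np.ndarray], events: list[FootprintEvent]) -> CoverStack:
    """Deterministically compose the visible cover stack from natural cover + events.

    Anthropogenic fractions are summed per class over events; natural cover
    fills the remainder in proportion to ``pnv``. If events oversubscribe a
    cell (total > 1) the anthropogenic fractions are rescaled to fit.
    """
    anth: dict[str, np.ndarray] = {}
    for ev in sorted(events, key=lambda e: e.origin_year):
        layer = anth.setdefault(ev.class_name, np.zeros(grid.shape))
        np.add.at(layer, (ev.rows, ev.cols), ev.fractions)
    total = np.zeros(grid.shape)
    for arr in anth.values():
        total += arr
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / np.where(over, total, 1.0), 1.0)
        for name in anth:
            anth[name] = anth[name] * scale
        total = np.minimum(total, 1.0)
    layers = {name: arr for name, arr in anth.items()}
    remainder = 1.0 - total
    for name, frac in pnv.items():
        layers[name] = frac * remainder
    return CoverStack(grid, layers)


def backcast(state: LandscapeState, target_year: int) -> LandscapeState:
    """Reconstruct the landscape at ``target_year`` by removing later footprint.

    Every event and crossing whose origin postdates the target year is
    dropped; affected cells revert to (renormalised) natural cover.
    """
    if target_year > state.year:
        raise ValueError(f"target_year {target_year} is after state year {state.year}")
    kept = [e for e in state.footprint_events if e.origin_year <= target_year]
    kept_crossings = [c for c in state.crossings if c.year_built <= target_year]
    return replace(state, year=target_year, footprint_events=kept, crossings=kept_crossings)


def reapply(state: LandscapeState, events: list[FootprintEvent], crossings: list[Crossing], year: int) -> LandscapeState:
    """Inverse of :func:`backcast`: add removed events back, advancing to ``year``."""
    return replace(
        state,
        year=year,
        footprint_events=state.footprint_events + list(events),
        crossings=state.crossings + list(crossings),
    )


@dataclass
class GrowthSpec:
    """Settlement growth fractions over a 30-year horizon, per municipality zone."""

    rural_growth_frac_30yr: float = 0.61
    canmore_growth_frac_30yr: float = 0.87
    banff_growth_frac: float = 0.0
    staging_order: tuple[str, ...] = ("growth_boundary", "area_to_be_determined")
    patch_size_exponent: float = 1.0

    def __post_init__(self):
        if min(self.rural_growth_frac_30yr, self.canmore_growth_frac_30yr, self.banff_growth_frac) < 0:
            raise ValueError("growth fractions must be non-negative")

    def scaled(self, factor: float) -> "GrowthSpec":
        """Growth spec with rural/Canmore growth scaled by ``factor`` (Banff stays fixed)."""
        return replace(
            self,
            rural_growth_frac_30yr=self.rural_growth_frac_30yr * factor,
            canmore_growth_frac_30yr=self.canmore_growth_frac_30yr * factor,
        )


def _patch_size_raster(settlement: np.ndarray) -> np.ndarray:
    """Per-cell size (in cells) of the 8-connected settlement patch, 0 outside."""
    labels, n = ndimage.label(settlement, structure=_STRUCTURE8)
    if n == 0:
        return np.zeros(settlement.shape)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return sizes[labels].astype(float)


def candidate_weights(state: LandscapeState, zone_mask: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Normalised sampling weights for new settlement cells within a zone.

    An undeveloped cell adjacent (8-neighbourhood) to settlement is weighted
    by the size of the largest adjacent patch raised to ``exponent``;
    non-adjacent cells get weight 0.
    """
    if not zone_mask.any():
        raise ValueError("zone is empty")
    settlement = state.settlement_mask()
    undeveloped = state.stack.anthropogenic_fraction() <= 0
    sizes = _patch_size_raster(settlement)
    neighbour_max = ndimage.maximum_filter(sizes, size=3)
    candidates = undeveloped & zone_mask & (neighbour_max > 0)
    weights = np.zeros(state.grid.shape)
    weights[candidates] = neighbour_max[candidates] ** exponent
    total = weights.sum()
    if total > 0:
        weights /= total
    return weights


def _allocate_cells(
    state_events: list[FootprintEvent],
    base_state: LandscapeState,
    n_cells: int,
    zone_masks: list[tuple[str, np.ndarray]],
    exponent: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick ``n_cells`` new settlement cells, staged through ``zone_masks`` in order.

    Works on a scratch settlement mask so adjacency emerges as cells convert;
    patch sizes are refreshed between sampling rounds.
    """
    current = base_state.with_events(state_events)
    settlement = current.settlement_mask().copy()
    developable = current.stack.anthropogenic_fraction() <= 0
    chosen_rows: list[int] = []
    chosen_cols: list[int] = []
    need = n_cells
    for zone_name, zone_mask in zone_masks:
        available = developable & zone_mask
        while need > 0 and available.any():
            sizes = _patch_size_raster(settlement)
            neighbour_max = ndimage.maximum_filter(sizes, size=3)
            candidates = available & (neighbour_max > 0)
            if not candidates.any():
                # no adjacency yet inside this zone: seed from the nearest
                # available cell to existing settlement
                dist = distance_to(settlement, current.grid)
                dist = np.where(available, dist, np.inf)
                idx = int(np.argmin(dist))
                r, c = np.unravel_index(idx, current.grid.shape)
                picks = (np.array([r]), np.array([c]))
            else:
                cand_idx = np.flatnonzero(candidates)
                w = neighbour_max.ravel()[cand_idx] ** exponent
                w = w / w.sum()
                k = min(need, cand_idx.size)
                sel = rng.choice(cand_idx, size=k, replace=False, p=w)
                picks = np.unravel_index(sel, current.grid.shape)
            chosen_rows.extend(picks[0].tolist())
            chosen_cols.extend(picks[1].tolist())
            settlement[picks] = True
            available[picks] = False
            need -= picks[0].size
        if need == 0:
            break
    if need > 0:
        raise AllocationError(zone_masks[-1][0] if zone_masks else "unknown")
    return np.asarray(chosen_rows, dtype=np.intp), np.asarray(chosen_cols, dtype=np.intp)


def forecast(
    state: LandscapeState,
    spec: GrowthSpec,
    horizon_years: int = 30,
    rng_seed: int | np.random.Generator = 0,
    exclude_mask: np.ndarray | None = None,
) -> list[LandscapeState]:
    """Simulate settlement expansion, returning one state per decade.

    Rural and Canmore settlement areas grow geometrically toward their
    30-year growth fractions; Canmore allocation is staged through the
    growth-boundary zone before the area-to-be-determined zone; Banff stays
    fixed. ``exclude_mask`` removes cells from consideration entirely (used
    by the limited-urban-expansion scenario).
    """
    if horizon_years < 10:
        raise ValueError("forecast horizon must be at least one decade")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    grid = state.grid
    cell_km2 = grid.cell_area_km2
    n_decades = horizon_years // 10

    settlement0 = state.stack.fraction("settlement")
    zone_specs = []  # (zone cells mask, 30yr growth fraction, staging masks)
    canmore_zone = state.zone("canmore")
    rural_zone = state.zone("rural")
    banff_zone = state.zone("banff")
    if exclude_mask is None:
        exclude_mask = np.zeros(grid.shape, dtype=bool)

    def staged_masks_for(zone_name: str, zone_mask: np.ndarray) -> list[tuple[str, np.ndarray]]:
        masks: list[tuple[str, np.ndarray]] = []
        if zone_name == "canmore":
            for stage in spec.staging_order:
                stage_mask = state.zone(stage) & ~exclude_mask
                if stage_mask.any():
                    masks.append((stage, stage_mask))
            remainder = zone_mask & ~exclude_mask
            for _, m in masks:
                remainder = remainder & ~m
            if remainder.any():
                masks.append((zone_name, remainder))
        else:
            masks.append((zone_name, zone_mask & ~exclude_mask))
        return masks

    if canmore_zone.any():
        zone_specs.append(("canmore", canmore_zone, spec.canmore_growth_frac_30yr))
    if rural_zone.any():
        zone_specs.append(("rural", rural_zone, spec.rural_growth_frac_30yr))
    # Banff: growth fraction is 0 by default; honour a non-zero value if configured
    if banff_zone.any() and spec.banff_growth_frac > 0:
        zone_specs.append(("banff", banff_zone, spec.banff_growth_frac))

    states: list[LandscapeState] = []
    events = list(state.footprint_events)
    allocated = {name: 0 for name, _, _ in zone_specs}
    initial_area = {
        name: float(settlement0[mask].sum()) * cell_km2 for name, mask, _ in zone_specs
    }

    for d in range(1, n_decades + 1):
        year = state.year + 10 * d
        new_rows: list[np.ndarray] = []
        new_cols: list[np.ndarray] = []
        for name, mask, g30 in zone_specs:
            target = initial_area[name] * (1.0 + g30) ** (10 * d / 30.0)
            need_cells = int(round((target - initial_area[name]) / cell_km2)) - allocated[name]
            if need_cells <= 0:
                continue
            working = state.with_events(events, year=year)
            rows, cols = _allocate_cells(
                events, working, need_cells, staged_masks_for(name, mask), spec.patch_size_exponent, rng
            )
            allocated[name] += need_cells
            new_rows.append(rows)
            new_cols.append(cols)
        if new_rows:
            ev = FootprintEvent(
                class_name="settlement",
                origin_year=year,
                rows=np.concatenate(new_rows),
                cols=np.concatenate(new_cols),
                fractions=np.ones(sum(r.size for r in new_rows)),
            )
            events = events + [ev]
        states.append(state.with_events(events, year=year))
    return states
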