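"""Movement-connectivity modelling on a resource-selection cost surface.

The cost of traversing a cell is 1 minus a permeability index derived from
a resource selection function (RSF): the RSF linear predictor is
exponentiated and min-max normalised to [0, 1] with bounds held fixed
across all time steps of a run so periods stay comparable. Two highway
modifications follow: permeability decays linearly to 0 within 500 m of
the highway, and highway cells are impassable barriers except at wildlife
crossing structures already built in the modelled year.

Connectivity is mapped with stochastic least-cost-path (LCP) ensembles:
start/end cells are drawn from collar-location cells, per-iteration
Normal noise perturbs the cost surface (movement is not perfectly
optimal), and all pairwise LCPs are accumulated into per-cell crossing
proportions, then binned into a 0-5 connectivity index on geometric
(exponentially spaced) thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ConfigurationError
from .footprint_history import LandscapeState
from .grid_core import Grid, distance_to

#: Truncation floor for perturbed per-cell costs (Normal draws can go negative).
COST_EPS = 1e-6
#: Additive edge-weight floor so zero-cost regions keep unique finite geodesics.
EDGE_EPS = 1e-9

HIGHWAY_DECAY_RANGE_M = 500.0

#: Synthetic default RSF coefficients (log scale). Signs follow regional
#: grizzly habitat findings: preference for low-elevation, gentle, vegetated
#: terrain; avoidance of development. Magnitudes are a documented default,
#: not an estimate — supply your own table for real analyses.
DEFAULT_RSF_COEFFICIENTS: dict[str, float] = {
    "forest": 1.0,
    "shrub": 0.8,
    "alpine": -0.5,
    "water": -1.0,
    "settlement": -3.0,
    "linear": -2.0,
    "recreation_facility": -1.5,
    "industrial": -3.0,
    "farmland": -1.0,
    "elevation_km": -4.0,
    "slope": -12.0,
}


@dataclass(frozen=True)
class PermeabilityModel:
    """RSF-style linear model on landscape covariates, normalised to [0, 1]."""

    coefficients: dict[str, float]
    bounds: tuple[float, float] | None = None  # fixed (min, max) of exp(lp)

    @classmethod
    def synthetic_default(cls) -> "PermeabilityModel":
        return cls(dict(DEFAULT_RSF_COEFFICIENTS))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PermeabilityModel":
        """Load coefficients from a (covariate, coefficient) table."""
        return cls(dict(zip(table["covariate"], table["coefficient"].astype(float))))

    def with_bounds_from(self, state: LandscapeState) -> "PermeabilityModel":
        """Freeze normalisation bounds on one reference state (usually current)."""
        raw = np.exp(linear_predictor(state, self))
        return replace(self, bounds=(float(raw.min()), float(raw.max())))


def covariates(state: LandscapeState) -> dict[str, np.ndarray]:
    """Covariate rasters computable from a landscape state."""
    from .grid_core import ANTHROPOGENIC_CLASSES, NATURAL_CLASSES

    cov = {name: arr for name, arr in state.stack.layers.items()}
    for name in (*ANTHROPOGENIC_CLASSES, *NATURAL_CLASSES):
        cov.setdefault(name, np.zeros(state.grid.shape))
    cov["elevation_km"] = state.elevation / 1000.0
    dzdy, dzdx = np.gradient(state.elevation, state.grid.cell_size)
    cov["slope"] = np.hypot(dzdx, dzdy)  # rise over run
    return cov


def linear_predictor(state: LandscapeState, model: PermeabilityModel) -> np.ndarray:
    cov = covariates(state)
    lp = np.zeros(state.grid.shape)
    for name, coef in model.coefficients.items():
        if name not in cov:
            raise ConfigurationError(f"model covariate {name!r} not computable from state")
        lp += coef * cov[name]
    return lp


def permeability(state: LandscapeState, model: PermeabilityModel) -> np.ndarray:
    """0-1 permeability: exp(linear predictor), min-max normalised.

    With no fixed bounds on the model, bounds default to this state's own
    range. A degenerate range (constant predictor) maps to 1 everywhere.
    """
    raw = np.exp(linear_predictor(state, model))
    lo, hi = model.bounds if model.bounds is not None else (float(raw.min()), float(raw.max()))
    if hi <= lo:
        return np.ones(state.grid.shape)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class CostSurface:
    """Per-cell traversal cost in [0, 1], barrier mask and open crossing cells."""

    grid: Grid
    cost: np.ndarray
    barrier: np.ndarray
    crossing_cells: np.ndarray  # boolean mask of barrier exemptions

    def passable(self) -> np.ndarray:
        return ~self.barrier | self.crossing_cells


def build_cost_surface(state: LandscapeState, model: PermeabilityModel) -> CostSurface:
    """Cost = 1 - permeability, with highway proximity decay and barrier.

    Permeability declines linearly to 0 within 500 m of the highway; highway
    cells are barriers except at crossings whose construction year is at or
    before the state's year.
    """
    perm = permeability(state, model)
    grid = state.grid
    barrier = np.zeros(grid.shape, dtype=bool)
    crossing_cells = np.zeros(grid.shape, dtype=bool)
    if (
        state.highway_mask is not None
        and state.highway_mask.any()
        and state.year >= state.highway_built_year
    ):
        d = distance_to(state.highway_mask, grid)
        perm = perm * np.minimum(d / HIGHWAY_DECAY_RANGE_M, 1.0)
        barrier = state.highway_mask.astype(bool).copy()
        for c in state.open_crossings():
            crossing_cells[c.row, c.col] = True
    return CostSurface(grid, 1.0 - perm, barrier, crossing_cells)


@dataclass
class PathEnsemble:
    """Accumulated least-cost paths: per-cell crossing counts and proportions."""

    grid: Grid
    n_paths: int
    crossing_count: np.ndarray
    n_excluded: int = 0

    @property
    def proportion(self) -> np.ndarray:
        if self.n_paths == 0:
            return np.zeros(self.grid.shape)
        return self.crossing_count / self.n_paths


@dataclass
class ConnectivityIndex:
    """0-5 connectivity level raster with its geometric bin edges."""

    grid: Grid
    level: np.ndarray
    bin_edges: np.ndarray  # upper edges of levels 1..5


def _neighbor_edges(grid: Grid, passable: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undirected 8-neighbour edge list over passable cells: (u, v, step length)."""
    n_rows, n_cols = grid.shape
    idx = np.arange(n_rows * n_cols).reshape(grid.shape)
    us, vs, ls = [], [], []
    for di, dj, step in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        r0, r1 = max(0, -di), n_rows - max(0, di)
        c0, c1 = max(0, -dj), n_cols - max(0, dj)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + di : r1 + di, c0 + dj : c1 + dj]
        ok = passable[r0:r1, c0:c1] & passable[r0 + di : r1 + di, c0 + dj : c1 + dj]
        us.append(a[ok])
        vs.append(b[ok])
        ls.append(np.full(ok.sum(), step * grid.cell_size))
    return np.concatenate(us), np.concatenate(vs), np.concatenate(ls)


def _edge_weights(u: np.ndarray, v: np.ndarray, lengths: np.ndarray, cost_flat: np.ndarray) -> np.ndarray:
    return lengths * 0.5 * (cost_flat[u] + cost_flat[v]) + EDGE_EPS


def eligible_cells(collar: pd.DataFrame, grid: Grid, min_points: int = 2) -> np.ndarray:
    """Flat indices of cells holding at least ``min_points`` collar locations."""
    cols = ((collar["x"].to_numpy() - grid.origin[0]) // grid.cell_size).astype(int)
    rows = ((collar["y"].to_numpy() - grid.origin[1]) // grid.cell_size).astype(int)
    ok = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    flat = rows[ok] * grid.n_cols + cols[ok]
    counts = np.bincount(flat, minlength=grid.n_rows * grid.n_cols)
    return np.flatnonzero(counts >= min_points)


def sample_paths(
    surface: CostSurface,
    collar: pd.DataFrame,
    n_start: int = 100,
    n_end: int = 100,
    n_iter: int = 10,
    rng_seed: int | np.random.Generator = 0,
    cost_sd: float | None = None,
) -> PathEnsemble:
    """Stochastic least-cost-path ensemble between collar-occupied cells.

    Start and end cells are sampled without replacement from cells with at
    least two collar locations. Each iteration redraws every cell's cost
    from Normal(cost, sd) truncated below at 1e-6 — one perturbed surface
    shared by all pairs of that iteration — and computes all
    ``n_start x n_end`` least-cost paths on it. ``cost_sd`` defaults to the
    standard deviation of cost across passable cells (set 0 to disable the
    perturbation). Pairs with no open route are excluded from the
    denominator with a warning.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    grid = surface.grid
    n_nodes = grid.n_rows * grid.n_cols
    passable = surface.passable()

    eligible = eligible_cells(collar, grid)
    eligible = eligible[passable.ravel()[eligible]]
    if eligible.size < n_start + n_end:
        raise ValueError(
            f"need {n_start + n_end} distinct eligible cells, found {eligible.size}"
        )
    sel = rng.choice(eligible, size=n_start + n_end, replace=False)
    starts, ends = sel[:n_start], sel[n_start:]

    if cost_sd is None:
        cost_sd = float(surface.cost[passable].std())

    u, v, lengths = _neighbor_edges(grid, passable)
    counts = np.zeros(n_nodes, dtype=np.int64)
    n_paths = 0
    n_excluded = 0
    for _ in range(n_iter):
        if cost_sd > 0:
            perturbed = rng.normal(surface.cost, cost_sd)
            perturbed = np.maximum(perturbed, COST_EPS)
        else:
            perturbed = surface.cost
        w = _edge_weights(u, v, lengths, perturbed.ravel())
        graph = csr_matrix((w, (u, v)), shape=(n_nodes, n_nodes))
        dist, pred = dijkstra(graph, directed=False, indices=starts, return_predecessors=True)
        for si in range(n_start):
            pred_row = pred[si]
            start_node = starts[si]
            for e in ends:
                if not np.isfinite(dist[si, e]):
                    n_excluded += 1
                    continue
                node = int(e)
                path_nodes = [node]
                while node != start_node:
                    node = int(pred_row[node])
                    path_nodes.append(node)
                counts[path_nodes] += 1
                n_paths += 1
    if n_excluded:
        warnings.warn(
            f"{n_excluded} start-end pair paths had no open route and were excluded"
        )
    return PathEnsemble(grid, n_paths, counts.reshape(grid.shape), n_excluded=n_excluded)


def path_cells(pred_row: np.ndarray, start: int, end: int) -> list[int] | None:
    """Reconstruct one path's flat cell indices from a predecessor row."""
    if pred_row[end] < 0 and end != start:
        return None
    node, out = int(end), [int(end)]
    while node != start:
        node = int(pred_row[node])
        out.append(node)
    return out[::-1]


def bin_connectivity(ensemble: PathEnsemble, ratio: float = 4.0) -> ConnectivityIndex:
    """Bin path proportions into a 0-5 index on geometric thresholds.

    Upper edges are t_k = p_max / ratio**(5-k) for k = 1..5, anchored at the
    maximum observed proportion; level k covers (t_{k-1}, t_k] with t_0 = 0,
    and proportion 0 maps to level 0.
    """
    prop = ensemble.proportion
    p_max = float(prop.max())
    if p_max == 0:
        warnings.warn("all-zero path ensemble; connectivity index is 0 everywhere")
        return ConnectivityIndex(ensemble.grid, np.zeros(ensemble.grid.shape, dtype=np.int8), np.zeros(5))
    edges = p_max / ratio ** (5 - np.arange(1, 6, dtype=float))
    level = np.digitize(prop, edges, right=True) + 1
    level = np.where(prop == 0, 0, np.minimum(level, 5)).astype(np.int8)
    return ConnectivityIndex(ensemble.grid, level, edges)
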