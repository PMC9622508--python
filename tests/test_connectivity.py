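import warnings

import numpy as np
import pandas as pd
import pytest

from corridorsim import connectivity as cn
from corridorsim.errors import ConfigurationError
from corridorsim.footprint_history import Crossing
from corridorsim.grid_core import Grid
from corridorsim.synthetic_valley import toy_landscape

from .oracles import exhaustive_min_path_cost


def _collar_at(cells, grid, n_per_cell=2):
    """Collar table with n points in each given (row, col) cell."""
    rows = []
    for r, c in cells:
        for k in range(n_per_cell):
            rows.append(
                {
                    "x": grid.origin[0] + (c + 0.3 + 0.2 * k) * grid.cell_size,
                    "y": grid.origin[1] + (r + 0.3 + 0.2 * k) * grid.cell_size,
                    "animal_id": 1,
                    "timestamp": pd.Timestamp("2019-06-01"),
                }
            )
    return pd.DataFrame(rows)


def _uniform_surface(n, cost_value=0.5):
    grid = Grid(n, n, 100.0)
    return cn.CostSurface(
        grid,
        np.full((n, n), cost_value),
        np.zeros((n, n), dtype=bool),
        np.zeros((n, n), dtype=bool),
    )


class TestPermeability:
    def test_zero_coefficients_degenerate_to_one(self, toy5):
        model = cn.PermeabilityModel({"forest": 0.0})
        assert np.array_equal(cn.permeability(toy5, model), np.ones((5, 5)))

    def test_valley_bottom_beats_steep_alpine(self, default_valley):
        _, state, _, _ = default_valley
        perm = cn.permeability(state, cn.PermeabilityModel.synthetic_default())
        natural = state.stack.anthropogenic_fraction() == 0
        bottom = natural & (state.elevation < 1400)
        alpine = natural & (state.elevation > 2200)
        assert perm[bottom].mean() > perm[alpine].mean()

    def test_settlement_scores_below_adjacent_natural(self, toy5):
        perm = cn.permeability(toy5, cn.PermeabilityModel.synthetic_default())
        assert perm[0, 0] < perm[0, 3]  # settlement cell vs natural forest cell

    def test_missing_covariate_rejected(self, toy5):
        with pytest.raises(ConfigurationError):
            cn.permeability(toy5, cn.PermeabilityModel({"moon_phase": 1.0}))

    def test_fixed_bounds_shared_across_states(self, toy5):
        model = cn.PermeabilityModel.synthetic_default().with_bounds_from(toy5)
        assert model.bounds is not None
        # with fixed bounds the same landscape reproduces the same surface
        assert np.array_equal(cn.permeability(toy5, model), cn.permeability(toy5, model))


class TestBuildCostSurface:
    def test_highway_proximity_decay(self, toy5):
        """At 250 m from the highway the permeability factor is exactly 0.5."""
        model = cn.PermeabilityModel({"forest": 0.0})  # permeability 1 everywhere
        surf = cn.build_cost_surface(toy5, model)
        hw = toy5.highway_mask.argmax(axis=0).max()
        # rows at distance 100, 200 m: factor d/500
        assert surf.cost[hw - 1, 0] == pytest.approx(1 - 100 / 500)
        assert surf.cost[hw - 2, 0] == pytest.approx(1 - 200 / 500)

    def test_beyond_500m_unmodified(self):
        toy = toy_landscape(20)
        model = cn.PermeabilityModel({"forest": 0.0})
        surf = cn.build_cost_surface(toy, model)
        far = np.abs(np.arange(20) - 10) * 100.0 >= 500
        assert np.allclose(surf.cost[far, 5], 0.0)

    def test_crossing_not_yet_built_is_barrier(self, toy5):
        import dataclasses

        past = dataclasses.replace(toy5, year=1970, crossings=[Crossing(2, 2, 1988)])
        surf = cn.build_cost_surface(past, cn.PermeabilityModel.synthetic_default())
        assert surf.barrier[2, 2] and not surf.crossing_cells[2, 2]
        current = dataclasses.replace(toy5, year=2020, crossings=[Crossing(2, 2, 1988)])
        surf2 = cn.build_cost_surface(current, cn.PermeabilityModel.synthetic_default())
        assert surf2.crossing_cells[2, 2]


class TestSamplePaths:
    def test_paper_design_path_count(self):
        surf = _uniform_surface(20, 0.4)
        cells = [(r, c) for r in range(20) for c in range(20)][:250]
        collar = _collar_at(cells, surf.grid)
        ens = cn.sample_paths(surf, collar, n_start=10, n_end=10, n_iter=3, rng_seed=0)
        assert ens.n_paths == 10 * 10 * 3

    def test_deterministic_paths_match_exhaustive_enumeration(self, rng):
        """With perturbation off, engine path costs equal brute-force optima."""
        for trial in range(4):
            n = 4 if trial % 2 else 5
            grid = Grid(n, n, 100.0)
            cost = rng.uniform(0.05, 1.0, (n, n))
            surf = cn.CostSurface(grid, cost, np.zeros((n, n), bool), np.zeros((n, n), bool))
            start, end = (0, 0), (n - 1, n - 1)
            u, v, lengths = cn._neighbor_edges(grid, surf.passable())
            from scipy.sparse import csr_matrix
            from scipy.sparse.csgraph import dijkstra

            w = cn._edge_weights(u, v, lengths, cost.ravel())
            graph = csr_matrix((w, (u, v)), shape=(n * n, n * n))
            dist = dijkstra(graph, directed=False, indices=[0])[0]
            expected = exhaustive_min_path_cost(cost, np.ones((n, n), bool), start, end, 100.0)
            assert dist[n * n - 1] == pytest.approx(expected, rel=1e-12)

    def test_straight_path_on_uniform_surface(self):
        surf = _uniform_surface(5, 0.5)
        collar = _collar_at([(2, 0), (2, 4)], surf.grid)
        ens = cn.sample_paths(surf, collar, n_start=1, n_end=1, n_iter=1, rng_seed=0, cost_sd=0.0)
        assert ens.n_paths == 1
        assert (ens.proportion[2, :] == 1.0).all()  # the straight row
        assert ens.proportion.sum() == 5.0  # and nothing else

    def test_barrier_soundness_on_toy(self, toy5):
        surf = cn.build_cost_surface(toy5, cn.PermeabilityModel.synthetic_default())
        collar = _collar_at([(0, 3), (0, 4), (4, 0), (4, 4)], toy5.grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = cn.sample_paths(surf, collar, n_start=2, n_end=2, n_iter=5, rng_seed=1)
        closed = surf.barrier & ~surf.crossing_cells
        assert (ens.crossing_count[closed] == 0).all()

    def test_isolation_when_all_crossings_closed(self, toy5):
        import dataclasses

        blocked = dataclasses.replace(toy5, crossings=[])
        surf = cn.build_cost_surface(blocked, cn.PermeabilityModel.synthetic_default())
        collar = _collar_at([(0, 0), (0, 4), (4, 0), (4, 4)], toy5.grid)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            ens = cn.sample_paths(surf, collar, n_start=2, n_end=2, n_iter=1, rng_seed=2)
        # south-side cells never reached from north-side starts and vice versa
        assert ens.n_excluded > 0
        south = ens.crossing_count[3:, :]
        north = ens.crossing_count[:2, :]
        assert south.sum() == 0 or north.sum() == 0 or ens.n_excluded >= 2

    def test_insufficient_eligible_cells_rejected(self):
        surf = _uniform_surface(5)
        collar = _collar_at([(0, 0)], surf.grid)
        with pytest.raises(ValueError):
            cn.sample_paths(surf, collar, n_start=2, n_end=2, n_iter=1)

    def test_raising_cell_cost_never_shortens_paths(self, rng):
        grid = Grid(5, 5, 100.0)
        cost = rng.uniform(0.1, 0.9, (5, 5))
        bumped = cost.copy()
        bumped[2, 2] += 0.5
        passable = np.ones((5, 5), bool)
        base = exhaustive_min_path_cost(cost, passable, (0, 0), (4, 4), 100.0)
        more = exhaustive_min_path_cost(np.minimum(bumped, 1.4), passable, (0, 0), (4, 4), 100.0)
        assert more >= base


class TestBinConnectivity:
    def _ensemble(self, proportions):
        grid = Grid(1, len(proportions), 100.0)
        counts = (np.asarray(proportions) * 10000).round().astype(int).reshape(1, -1)
        return cn.PathEnsemble(grid, 10000, counts)

    def test_stated_edge_formula(self):
        ens = self._ensemble([0.0, 0.0025, 0.01, 0.04, 0.16, 0.64, 0.001])
        idx = cn.bin_connectivity(ens, ratio=4.0)
        assert np.allclose(idx.bin_edges, [0.0025, 0.01, 0.04, 0.16, 0.64])
        assert idx.level.tolist()[0] == [0, 1, 2, 3, 4, 5, 1]

    def test_zero_proportion_is_level_zero_and_max_is_five(self, rng):
        p = rng.random((4, 6))
        p[0, 0] = 0.0
        counts = (p * 1000).astype(int)
        ens = cn.PathEnsemble(Grid(4, 6, 100.0), 1000, counts)
        idx = cn.bin_connectivity(ens)
        assert idx.level[0, 0] == 0
        assert idx.level[np.unravel_index(counts.argmax(), counts.shape)] == 5

    def test_level_monotone_in_proportion(self, rng):
        p = np.sort(rng.random(50))
        ens = cn.PathEnsemble(Grid(1, 50, 100.0), 10000, (p * 10000).astype(int).reshape(1, -1))
        levels = cn.bin_connectivity(ens).level[0]
        assert (np.diff(levels) >= 0).all()

    def test_all_zero_warns(self):
        ens = cn.PathEnsemble(Grid(2, 2, 100.0), 0, np.zeros((2, 2), dtype=int))
        with pytest.warns(UserWarning):
            idx = cn.bin_connectivity(ens)
        assert (idx.level == 0).all()
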