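# corridorsim

Cumulative-effects scenario simulation of wildlife movement connectivity and
human–wildlife conflict risk on raster landscapes.

`corridorsim` is built for landscape ecologists and land-use planners who want
to ask "what has decades of settlement growth and recreation done to a
movement corridor, and what would mitigation buy us?" at a regional scale —
the scale project-by-project environmental assessment misses. The study system
it emulates is a developed mountain valley (two towns, hamlets, a fenced
highway with sparse wildlife crossings, a growing trail network) used by
grizzly bears; every input is produced by a seeded synthetic-valley generator,
so the full pipeline runs and is testable without any proprietary GIS,
heatmap, or GPS-collar data.

## The model

The pipeline chains five stages on a shared 100 m raster grid:

1. **Footprint history.** Land cover is stored as per-cell cover fractions
   plus a list of dated footprint events (patch, class, origin year).
   Backcasting removes events dated after a target year and restores natural
   cover; forecasting grows settlement outward from existing patches with
   probability ∝ (adjacent patch area)^γ, staged through planning zones, with
   per-decade multipliers `(1+g)^(1/3)` derived from 30-year growth fractions
   (rural +61%, Canmore +87%, Banff fixed).
2. **Recreation activity.** A heatmap-style 0–5 level raster is linked to
   absolute activity by an exponential scale `A(k) = A₀·g^(k−1)`; histories
   and forecasts conserve zone totals against population growth, splitting new
   activity 50/50 between intensified existing trails and new informal trails
   within 2 km of new settlement.
3. **Cost surface.** A resource-selection-function (RSF) linear predictor over
   cover fractions, elevation and slope is exponentiated and min–max
   normalised to a 0–1 permeability index `p` (bounds fixed across time steps);
   cost = 1 − p. Permeability decays linearly to 0 within 500 m of the
   highway, and highway cells are absolute barriers except at wildlife
   crossings already built in the modelled year.
4. **Stochastic least-cost paths.** Start/end cells are drawn from cells with
   ≥ 2 collar locations; each iteration redraws every cell's cost from
   `Normal(cost, σ)` (σ = study-area s.d. of cost, truncated at 10⁻⁶) and
   computes all pairwise least-cost paths on an 8-connected grid graph
   (edge weight = step length × mean endpoint cost). Per-cell path
   proportions are binned into a 0–5 connectivity index on geometric
   thresholds `t_k = p_max / r^(5−k)`.
5. **Conflict risk.** Risk = (400 m focal mean of connectivity level) ×
   (400 m focal mean of activity level) ∈ [0, 25], classified as very low
   (0, 1], low (1, 4], moderate (4, 9] and high (> 9].

Scenarios — limited urban expansion, no informal trails, restricted
recreation — act through pre-scaled growth inputs or map-level activity rules
and are compared to the Base Case by the extent of moderate-or-high risk.

## Worked example

```python
import warnings

from corridorsim.synthetic_valley import ValleyConfig, generate_landscape
from corridorsim import connectivity as cn
from corridorsim.conflict import risk_index, CATEGORY_CODES
from corridorsim.grid_core import area_report

# a 4 km x 6 km valley keeps this example fast; the default is 20 km x 45 km
cfg = ValleyConfig(n_rows=40, n_cols=60, n_collar_cells=250, rng_seed=11)
state, activity, collar = generate_landscape(cfg)

report = area_report(state.stack)
print(f"development footprint: {report.total_footprint:.2f} km2 "
      f"({100 * report.total_footprint / state.grid.extent_km2:.1f}% of the study area)")

model = cn.PermeabilityModel.synthetic_default().with_bounds_from(state)
surface = cn.build_cost_surface(state, model)
ensemble = cn.sample_paths(surface, collar, n_start=100, n_end=100, n_iter=10, rng_seed=1)
print(f"least-cost paths accumulated: {ensemble.n_paths:,}")

index = cn.bin_connectivity(ensemble)
risk = risk_index(index, activity)
for name, code in CATEGORY_CODES.items():
    km2 = (risk.category == code).sum() * state.grid.cell_area_km2
    print(f"  {name:<9} {km2:6.2f} km2")
```

prints

```
development footprint: 1.23 km2 (5.1% of the study area)
least-cost paths accumulated: 100,000
  none       15.71 km2
  very_low    4.00 km2
  low         4.09 km2
  moderate    0.20 km2
  high        0.00 km2
```

i.e. about 5% of this little valley is developed, the 100 start × 100 end ×
10 iteration sampling design accumulated exactly 100,000 paths, and the cells
where high-connectivity corridors overlap recreation concentrate into a small
moderate-risk fringe (0.20 km²) around the towns.

The full timeline-and-scenario sweep is one call (or
`corridorsim simulate --seed 1 --scenarios base,no_informal_trails`):

```python
from corridorsim.pipeline import RunConfig, run
result = run(RunConfig(rng_seed=1, scenarios=("base", "no_informal_trails")), workdir="outputs")
print(result.extents)   # tidy (year, scenario, category, km2, pct_change_vs_base)
```

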