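# Methods

This note documents the models behind `corridorsim`, the parameters that
matter, what the synthetic landscape does and does not emulate, and the
numerical choices a careful user should know about.

## Landscape representation

Space is a single row-major grid of 100 m cells in a planar metric frame
(no geographic CRS; cell centres at `origin + (i+0.5)·cell_size`). Land
cover is fractional: every cell carries fractions of four natural classes
(forest, shrub, alpine, water) and five anthropogenic classes (linear,
recreation_facility, settlement, industrial, farmland) summing to 1 ± 1e-9.
Class area is the exact sum of fractions × cell area, so area accounting is
additive by construction.

A landscape state separates *potential natural cover* (what each cell would
be with no development) from a list of dated footprint events. The visible
stack is a pure deterministic function of the two: anthropogenic fractions
are summed over events active at the state's year (rescaled in the rare
oversubscribed cell) and natural cover fills the remainder in proportion to
the potential composition. Because backcasting only filters the event list
and the stack is recomposed by the same function, backcast followed by
re-applying the removed events reproduces the current stack bit-for-bit.

## Footprint history

*Backcast*: remove all events (and wildlife crossings) whose origin
postdates the target year. *Forecast*: settlement area in each municipality
zone grows toward a 30-year fraction with a geometric per-decade multiplier
`(1+g)^(1/3)` (only the 30-year totals are specified, so constant
proportional growth is assumed). Defaults: rural +61%/30 yr, Canmore
+87%/30 yr (the netted-out figure after ~10% infill; infill itself is not
modelled), Banff 0 (expansion prohibited inside a national park).

New cells are whole-cell conversions to 100% settlement, drawn without
replacement from undeveloped cells 8-adjacent to existing settlement with
weight `(area of largest adjacent patch)^γ`, γ = 1 by default
(config-exposed; the functional form of the patch-size bias is otherwise
unconstrained, and a power law is the simplest monotone choice). Patch
sizes come from 8-connected component labelling and adjacency is refreshed
between sampling rounds, so adjacency "emerges" as patches grow. Canmore's
allocation is staged: growth-boundary cells are exhausted before
area-to-be-determined cells; if a stage has no adjacent candidate but still
has room, the nearest available cell to existing settlement seeds it.
Exhausting all stages raises an allocation error naming the zone.

## Recreation activity

Activity is kept in two co-registered rasters: absolute activity (arbitrary
units) and a heatmap-style level in {0..5} linked by `A(k) = A₀·g^(k−1)`,
`A(0) = 0`; the inverse is floor-log binning clamped to [1, 5]. The
exponential base defaults to g = 3 with A₀ = 1 — the published calibration
data (trail counts behind the heatmap levels) is not available, so the
scale is an order-of-magnitude free parameter, config-exposed. A
consequence used throughout: categorical levels change more slowly than
absolute activity.

*Backcast*: activity in recreation-facility cells, and within 2 km of
settlement patches, is removed wherever that footprint postdates the target
year (the removal is tied to the dated patch, not to settlement per se);
the rest is rescaled by a single factor so regional totals follow the
configured population trajectory (default +30%/decade historically).
*Forecast*: each municipality's total new activity equals its population
growth fraction × current zone total, split half onto existing trail cells
(proportional to current use) and half onto new informal random-walk trails
within 2 km of that decade's new settlement cells (constrained to the zone
so zone totals balance to < 0.1%); Banff instead intensifies existing
trails by 25%/decade with no new trails.

*Scenarios*: `no_informal_trails` zeroes activity off designated trails and
off development footprint; `restricted_recreation` halves activity at
distance ≥ 100 m from settlement; `limited_urban_expansion` scales Canmore
settlement and activity growth inputs to 15% of the Base Case and excludes
the area-to-be-determined from footprint allocation (so it is an input
modifier, not a map rule). All scenario activity is cellwise ≤ the Base
Case by construction.

## Permeability, cost and paths

Permeability is `exp(Xβ)` min–max normalised to [0, 1], with the bounds
frozen on one reference state (the current landscape) and shared across all
time steps of a run so periods are comparable; a degenerate constant
predictor maps to 1 everywhere. The default coefficient table is
*synthetic*: signs encode preference for low-elevation, gentle, vegetated
terrain and avoidance of development, but magnitudes are a documented
default, not an estimate — real analyses should load their own RSF table
(`PermeabilityModel.from_table`).

Cost = 1 − permeability after two highway modifications: a linear decay
factor `min(d/500 m, 1)` on permeability, and an absolute barrier on
highway cells except crossings with `year_built ≤ state.year` (the barrier
applies whenever the highway exists in the modelled year).

Paths run on an 8-connected grid graph; edge weight = step length (100 m
cardinal, 100·√2 m diagonal) × mean of the two endpoint cell costs, plus a
10⁻⁹ floor so zero-cost regions keep unique finite geodesics. Start and end
cells (default 100 + 100) are sampled without replacement from cells
holding ≥ 2 collar locations. Sub-optimal movement is represented by
per-iteration perturbation: one redrawn surface per iteration — every
cell's cost ~ Normal(cost, σ) truncated below at 10⁻⁶, σ = the s.d. of
cost over passable cells — shared by all pairs of that iteration (one
single-source shortest-path computation per start point per iteration; a
per-pair redraw would cost 100× more for little statistical difference).
Ties among equal-cost paths break deterministically by predecessor scan
order; the perturbation makes exact ties measure-zero in production runs.
Pairs left disconnected (e.g. all crossings closed) are excluded from the
denominator with a warning.

Per-cell path proportions are binned into the 0–5 connectivity index on
geometric upper edges `t_k = p_max / r^(5−k)`, r = 4, anchored at the
maximum observed proportion (level k covers `(t_{k−1}, t_k]`, 0 stays 0).
Anchoring at `p_max` rather than a fixed constant keeps the index
scale-free across ensemble sizes; r is config-exposed.

## Conflict risk

Risk = focal-mean(connectivity level) × focal-mean(activity level) over a
circular 400 m window (centre distance ≤ radius, focal cell included —
the buffer-based precedent for the 400 m figure is radial, so the value is
treated as a radius; flagged in config). Edge windows shrink to in-bounds
cells rather than padding, avoiding a zero bias at the boundary. The index
lies in [0, 25] and is classified very low (0, 1], low (1, 4], moderate
(4, 9], high (> 9], with exactly-zero cells given a separate "none" code so
the classification is a total function. Extents are cell counts × cell
area; percent change of the moderate∪high extent is reported against the
Base Case of the same year.

## The synthetic valley

The generator emulates the structure the analysis relies on, not any real
place: a parabolic U-shaped valley (floor 1300 m, relief 1200 m) with a
low-amplitude smooth random field; natural cover assigned by elevation band
with logistic transitions and a meandering river strip; footprint
concentrated on the valley floor as dated patch events (settlement cores
pre-1950 with growth rings through 2015, highway 1955, railway 1920,
recreation facilities, quarries, a farm) totalling ~4–5% of the 900 km²
study area; a full-width highway row with five crossings built 1988–2030;
trails random-walked outward from settlement edges (40% informal) with
activity decaying with settlement distance so > 80% of absolute activity
falls within 2 km of settlement (violations raise a generation error);
collar points placed in ~400 distinct natural cells with probability ∝
permeability², guaranteeing the 100 + 100 sampling design is feasible and
collar density correlates with habitat preference.

What it does *not* emulate: hydrology, vegetation succession, calibrated
visitation totals, traffic, attractants, or the actual geography of any
valley. Passing tests therefore demonstrate that the *method* behaves as
specified (conservation, round trips, barrier soundness, displacement and
dominance directions) — not that the published regional magnitudes (e.g.
specific percent reductions) recur, which depend on proprietary inputs.

## Problem sizes and determinism

The default grid is 200 × 450 (900 km²). The full sampling design
(100 × 100 × 10 = 100,000 paths per landscape) runs in a couple of minutes
per landscape at that size; the bundled scenario sweeps use a reduced
ensemble (40 × 40 × 3 per landscape) and the test profile uses a 50 × 80
grid with 20 × 20 × 2 paths, sizes chosen to keep a full timeline sweep in
the minutes range on one CPU while staying out of the degenerate
small-ensemble regime. One top-level seed hash-derives per-stage
substreams, so a fixed config + seed reproduces every raster and the run
manifest hash exactly.

## Known limitations

- Least-cost paths assume movement minimises accumulated cost between known
  endpoints; no home-range, memory or attractant behaviour.
- Constraining endpoints to collar cells inside the study area exaggerates
  east–west movement along the valley axis.
- The activity model extrapolates current spatial patterns; no agent-based
  recreation or trail-formation dynamics.
- Whole-cell settlement conversion ignores densification and demolition.
- The default RSF table is synthetic; absolute permeability values carry no
  biological calibration.
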