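# Methods

## Model of the stream network

All computation happens on a north-up, cell-edge-registered geographic grid
(default cell size 1/120°, i.e. 30 arc-seconds; the near-global reference
layout spans 145°W–180°E and 60°N–56°S, 39,000 × 13,920 cells). Drainage is
single-direction D8: every cell routes to exactly one of its eight
neighbours by steepest descent, with drop computed as Δz divided by step
length (1 for cardinal, √2 for diagonal moves). Ties resolve by the fixed
neighbour scan order E, SE, S, SW, W, NW, N, NE, so routing is
bit-reproducible. Multiple-flow-direction routing is deliberately out of
scope: under D8 every stream cell's sub-catchment is a well-defined set and
the sub-catchments of a confluence's donors partition its own, which the
per-cell watershed logic and the quality-control arithmetic both rely on.

## DEM conditioning

* **Carving** lowers the DEM by a fixed depth (default 22 m) along a known
  channel mask so routed flow stays in the mapped channels. The carved
  surface is used for routing only; elevation metrics always read the raw
  DEM. A diagnostic (`carving_depth_profile`, CLI `carve-profile`) reports,
  for a stepped series of depths (default 0–40 m in 2 m steps), how many
  mapped stream cells fail to re-emerge as routed streams — a concrete
  operationalisation of "checking downstream connectivity", which the
  original production procedure left informal.
* **Per-order smoothing** replaces each ordered stream cell with the mean
  of same-order cells in its 3×3 window (window configurable, odd ≥ 3).
  Orders never mix, so a tributary joining a main stem does not bleed its
  values across the confluence; a cell with no same-order neighbour keeps
  its value.
* **Depression filling** is priority-flood with an epsilon gradient,
  seeded from the grid edge and from cells adjacent to NoData (both can
  drain off the data area). Epsilon defaults to ten times the float64
  spacing at the largest absolute elevation — the smallest increment
  guaranteed representable — so strict descent exists everywhere while
  elevations are not measurably distorted. No cell is ever lowered, and
  filling is idempotent. An interior flat cell surviving to the routing
  stage is a hard error naming the cell, not a silent sink.

## Sub-catchments, distances, weights

Each stream cell is a pour point; its sub-catchment is found by breadth-
first search over the donor graph. Two distance fields feed the inverse-
distance weighting `w = 1/d`:

* **Euclidean** (`catchment` domain): √(Δrow² + Δcol²) in cell units over
  all member cells. No geodesic latitude correction is applied — distances
  are in grid-cell units by design, matching the cell-based weighting of
  the original procedure.
* **Along-network** (`watercourse` domain): flow-path step count from each
  member stream cell to the outlet. Paths may traverse non-stream cells
  (values are only reported on stream cells). Diagonal steps count 1 by
  default — the topological reading of "grid cells as spatial units"; a
  √2-per-diagonal metric is available via `diagonal_sqrt2=True`. Whether
  diagonal along-network steps should count 1 or √2 is genuinely open; the
  default was fixed once and both options are tested.

`w = 1/d` is undefined at the outlet (d = 0), so the outlet — and only it —
is assigned d = 1: its weight is the maximum, 1, weights are bounded in
(0, 1], and no downstream special-casing is needed. A consequence is that
the outlet and a cell one step upstream share weight 1.

## Aggregation and variable domains

Seven metrics (min, max, range, average, sum, weighted average, weighted
sum) over one of the two domains. Temperature variables — and the
temperature-based bioclim variables — aggregate over the *water courses*
with network weights; precipitation, land cover, soil and geology aggregate
over the *full sub-catchment* with Euclidean weights. Geology uses only the
weighted sum, modelling surface-lithology influence as dampened along the
river continuum rather than accumulated. NoData source cells are ignored;
an all-NoData domain yields NoData, never an exception.

Bioclim variables are computed **after** upstream aggregation: each stream
cell's 19 values derive from its 36 upstream-aggregated monthly values
(12 × tmin, tmax, prec), not from aggregating locally-computed bioclim
layers. Quarters are the twelve wrap-around 3-month windows with ties going
to the earliest window (determinism). bio3 is defined as 0 when bio7 = 0;
bio15 uses the 1 + bio12/12 denominator so arid cells stay finite (a plain
mean denominator is available by flag).

## Storage schema

The 324-band catalog (`fwstream.catalog.layer_catalog`) is the single
source of truth for file names, band order, units, scale factors, datatypes
and NoData codes: temperatures ×10 (Int32, NoData −999), slope ×100, soil
pH ×10, the unitless bioclim ratios bio3/bio15 ×100, precipitation as
Float64 (NoData −9999), land cover as signed 8-bit (NoData −127), geology
weighted counts as Int32 (NoData −9999). Scaling truncates toward zero
rather than rounding — the storage default of the original integer layers.
"Byte −127" is read as signed 8-bit with NoData −127, the only consistent
reading of that printed pair. GeoTIFF intermediates carry the standard
georeferencing tags; final families are multiband netCDF (classic
container via the scipy backend, the writer available here) with per-band
codes and schema recorded as attributes, and write/read round-trips are
bit-identical on stored integers. One historical note: the reference
catalog's printed table repeats the file name `monthly_tmin_average.nc`
for the tmax and weighted families and embeds a space in
`soil_weighted average.nc`; this package uses systematic per-family names
(`monthly_tmax_average.nc`, `soil_weighted_average.nc`, …) and treats the
repeats as typesetting errors.

## Lakes and reservoirs

Lake units are maximal connected components of the lake mask, connectivity
4 by default (the clumping default of the original toolchain; 8 by flag).
Units intersecting the stream network receive the mean of their valued
(fish-bone stream) cells over every unit cell; non-intersecting units stay
NoData. The source product's ">0.1 km²" polygon filter is sub-cell at 1 km
grain and is exposed honestly as a `min_cells` threshold (default 1). The
shoreline interface — cells where stream and lake meet under 8-adjacency,
on both sides — is then smoothed by the 3×3 mean of valued neighbours.
Both operations stay within the input value range, and unit averaging is
idempotent.

## Quality control

An order-k stream cell must drain at least `min_cells(k) = 2^k − 1` cells
(1 for k = 1). Cells below the bound are flagged as truncated and repaired
iteratively: each pass, every flagged cell with at least one *unflagged*
valued same-order cell in its 3×3 window takes the **maximum** of those
values (truncation biases summaries low, so the maximum neighbour is the
best local proxy) and becomes unflagged. Donor values are frozen at the
start of each pass, so repairs propagate one neighbourhood per iteration;
the flagged count strictly decreases until a fixpoint or the iteration cap
(default 50 — the original procedure iterates unboundedly "until filled",
which need not terminate on pathological masks; leftovers are reported,
not raised). Manually-identified over-estimated reaches arrive as a user
removal mask, are blanked to each layer's NoData, and are exported as the
catalog's `cells_removed` band alongside `missing_cells`.

The flag criterion compares *total* accumulation (all upstream cells)
against minima that count stream cells — a valid lower bound, since total
accumulation is at least the stream-cell count.

## Synthetic fixtures: what they emulate, what they don't

* **Valley basins**: an analytic V-shaped surface draining to one southern-
  edge outlet, plus seeded uniform interior noise bounded by
  `relief/nrows`. Noise is added *before* filling so the pit-removal path
  is genuinely exercised; boundaries stay analytic so the outlet remains
  the unique edge sink and whole-grid accumulation at the outlet equals
  nrows × ncols — the conservation oracle used throughout the tests.
* **Minimal Strahler networks**: the combinatorial minimum for order k is
  `2^k − 1` cells (complete binary merge tree, each confluence joining two
  equal-order children). On a D8 grid this minimum is *achievable only for
  k ≤ 6*: every cell of the tree lies within Chebyshev radius k − 1 of the
  outlet, and `2^k − 1 > (2k − 1)²` for k ≥ 8; exhaustive search
  (`scripts/search_tree_embeddings.py`) shows depth 6 (order 7) is likewise
  infeasible even though the counting bound would permit it. Exact
  embeddings for k ≤ 6, found by that search, are frozen as tables; for
  k ≥ 7 two order-(k−1) networks are joined through shortest BFS connector
  reaches (order is exact, cell count larger: 163, 349 and 745 cells for
  orders 7, 8, 9). The `2^k − 1` QC rule is therefore a strict lower bound
  for high orders on grid data — slightly conservative, never wrong.
* **Environmental layers**: constants, linear north-south gradients, seeded
  uniform noise, and 12 integer class-fraction layers summing to exactly
  100 per cell (largest-remainder rounding of random weights).
* **Lakes**: unions of seeded rectangles.

What the fixtures do **not** emulate: realistic terrain autocorrelation,
braided or looped channels, endorheic basins, latitude-dependent cell
areas, coastal NoData fringes, or the error structure of upscaled real
hydrography. Green tests therefore demonstrate algorithmic correctness
(against brute-force oracles and exact invariants), not fitness of any
particular real-world dataset.

## Problem sizes and determinism

The test suite runs basins up to 32×32 (oracle comparisons are exhaustive
there) and one full 128×128 end-to-end pipeline (~1,800 stream cells,
about 15 s single-threaded); these sizes were chosen as the smallest at
which every code path (multi-order networks, lakes crossing streams, QC
flags) is exercised. Every generator and algorithm is a pure function of
its inputs and seed; chunked sub-catchment processing is defined so chunks
are independent work units merged in row-major outlet order, making any
parallel schedule reproduce the serial result.
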