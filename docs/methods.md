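# Methods

This note records the models the package implements, the parameters that
matter, the numerical conventions, and the design choices made where the
published scheme left the design open.

## Raster model

All layers are square-cell rasters ("grids") with row 0 at the northern
edge, values referring to cell centres, and areas counted as
cells × cellsize². Multi-grid operations require *alignment*: identical
shape, cell size and top-left origin — heterogeneous inputs must be
resampled to one template before analysis (the synthetic generator emits
aligned bundles directly). Nodata is NaN internally and a sentinel
(−9999 by default) on disk; any arithmetic with a nodata operand yields
nodata. Supported formats are Esri ASCII grid and single-band GeoTIFF
(pixel-scale, tiepoint and nodata tags); reprojection and multi-band
imagery are out of scope.

Natural-breaks classification uses the exact Fisher–Jenks dynamic program
(divide-and-conquer over the concave-Monge cost, O(k·n log n)), which
minimizes total within-class sum of squared deviations and is fully
deterministic. Rasters with more than 10 000 valid cells are classified
from a uniform row-major stride subsample of 10 000 values — deterministic
by construction, no RNG — so classification is reproducible at any raster
size. Interior break values are the upper edge of each class;
classification is left-open/right-closed (a value on a break falls in the
lower class).

## Assessment

Sensitivity formulas are applied to *graded* factor values (1–9), not raw
physical values: the ordinal assignment exists precisely to make rainfall
erosivity, soil texture, relief and coverage commensurable before the
geometric mean, and it bounds every index in [1, 9]. Band membership for
continuous factors is left-open/right-closed; vegetation coverage grades
descending (high coverage → low sensitivity). Negative monthly
rainfall-erosivity terms (months below ≈8.67 mm) are retained; subsequent
natural-breaks grading makes the absolute level immaterial.

Soil texture is carried as the 13-class USDA texture index (1 = heavy clay
… 13 = sand; 14 accepted for gravel). The same code feeds two places: the
sensitivity grade (via a code→grade map: silt lowest, loams moderate, sand
and clays high, gravel highest) and the soil-percolation factor
F_sic = code/13.

Service-importance inputs are min–max normalized to [0, 1] before
multiplication. The published formulas never state a scaling, but
unnormalized NPP·rainfall·temperature products would be unit-dependent
while the downstream Jenks classes are scale-free; normalization makes the
[0, 1] range of each index an enforceable invariant. Two inputs are not
min–max normalized because they have natural scales: F_sic (code/13,
already in (0, 1]) and the slope factor F_sio = slope°/90 (slope from the
DEM by Horn's 3×3 method, edge cells via replication padding). The graded
soil layer enters S_pro as grade/9 rather than a per-map min–max, so a
landscape with uniform soil does not degenerate. F_alt, which appears only
inside the biodiversity index, is taken as min–max normalized elevation:
the (1 − F_alt) term then discounts the coldest, highest terrain.

The sensitivity and importance composites use weights 0.43/0.39/0.18 and
0.45/0.30/0.25; their superposition uses 0.5/0.5. The equal weighting is
the neutral reading of "spatial superposition" and is configurable. The
integrated score min–max normalizes both composites first, so neither
dominates through units. Composites whose weights do not sum to 1 are
accepted with a logged warning (the values are used as given).

## Sources

The extremely-important class (class 5 of 5) is labelled with
8-connectivity (diagonal contact counts — the usual convention for
landscape patch delineation; 4-connectivity is available). Patches whose
minimum distance is strictly below 500 m are merged transitively
(union–find over the pairwise predicate); distance is measured between
nearest cell centres via per-patch Euclidean distance transforms, the
raster analogue of edge-to-edge distance (aggregation of adjacent habitat
is the ecological intent; centroid distance would under-merge elongated
patches). Merged sources remain multi-part — gap cells stay background —
so area and land-use composition statistics are not inflated. The area
filter keeps patches strictly larger than 8 km², relabelled densely in
descending area order.

## Resistance

The five factor band tables map raw layers to {1, 20, 40, 60, 80, 100};
band edges are left-open/right-closed. The published road tables assign
resistance 1 — *below* the nearest band's 20 — beyond 800 m (county roads)
and 2000 m (highways). This non-monotone step is reproduced verbatim by
default; a `monotone_roads` flag replaces the 1 by 20 for sensitivity
analysis. Factor weights default to the published values
0.095/0.213/0.236/0.118/0.173. These sum to 0.835 and are *not* the
principal eigenvector of the published comparison matrix
(0.048/0.316/0.371/0.102/0.164); the pipeline uses the printed values to
reproduce the published scheme as stated, and the AHP module recomputes
eigenvector weights from any supplied matrix for users who prefer a
self-consistent set.

## Connectivity

The MCR formulation includes an unspecified monotone-increasing function
f_min; it is taken as the identity, since any monotone transform preserves
the ranking of path costs and therefore every least-cost path. Movement is
on the 8-connected cell graph with step cost = mean endpoint resistance ×
step length (cellsize orthogonally, ×√2 diagonally) — the de-facto grid
cost-distance convention. Shortest paths are computed with a binary-heap
Dijkstra (via scipy's csgraph); path backtracking follows the predecessor
array and endpoint ties resolve to the smallest (row, column) index, so
paths are deterministic across runs and platforms.

Corridor pairs default to *allocation adjacency*: a corridor is built for
every pair of sources whose cost-allocation regions share a cell boundary
(the core-adjacency rule of corridor-mapping tooling); `all_pairs` is
available. Disconnected pairs are reported explicitly with infinite cost,
never as exceptions.

Pinch points use pairwise circuit theory solved directly on the graph
Laplacian. The corridor swath is the set of cells whose
cost-from-a + cost-from-b exceeds the pair cost by at most 5% (the
published workflow never states a corridor width; 5% slack is the
default and configurable). Each source patch is contracted to a terminal;
one unit of current is injected at one terminal and the other grounded;
edge conductance is 1/step-cost; the reduced sparse system is solved
directly. Cell current is half the sum of absolute incident edge currents,
which makes every interior cell of a series chain carry exactly 1.
Swath pockets not connected to both terminals are excluded before solving,
so the system is never singular; a pair with no connection reports a
disconnected result. Per-corridor maps are combined by cellwise maximum,
split general/important by a 2-class natural-breaks cut of the positive
currents (a constant field, which admits no cut, is all general), and
important patches larger than 1 km² become the important nodes.

## Zoning

Safety zones are a five-class natural-breaks cut of the cumulative
cost-distance surface from the sources (zone 1 = lowest cost = highest
safety); a flag classifies the raw weighted resistance surface instead,
since the published description is ambiguous about the basis. The policy
coarsening follows the published headline statement: zone 1 →
conservation, zones 2–3 → control, zones 4–5 → restoration (elsewhere the
same source text calls the high-safety class "development"; the mapping is
fully configurable, which covers both readings).

## Synthetic landscapes

The generator emulates the statistical structure of the real inputs of a
subtropical monsoon basin: a spatially autocorrelated DEM
(Gaussian-smoothed random fields, correlation range ≈10 cells) with a
northwest-high/southeast-low trend; ~1700 mm/yr rainfall on a wet-season
monthly profile, positively correlated with elevation; temperature by
lapse rate; aridity anti-correlated with rainfall; patchy USDA soil-texture
mosaics; a land-use map with ~80% forest/grass, cultivated lowlands,
construction clustered within 2 km of roads, a river line, and rare bare
ground; vegetation coverage and NPP positively correlated with each other
and depressed near roads. Default scale is 200×200 cells at 1 km — the
analysis scale the band tables (relief in metres over a 37×37 window,
road-distance bands in hundreds of metres) are written for.

Six high-value habitat patches are *planted* as plateau-profile blobs
(radius 5 cells) kept clear of roads and of each other. Inside them the
generator raises rainfall (+35%), aridity (+0.30), sand-blowing days
(+140), and NPP (×2.2), sets sandy soil, moderate (grass/shrub) coverage
and adds moderate terrain ruggedness — a coherent "sensitive and
service-rich upland" signature that the assessment should flag as
extremely important. The truth record stores the centres so
structure-recovery tests can verify that source extraction finds them.

What the generator does **not** emulate: real geography or CRS, station
interpolation artefacts, land-use misclassification noise, seasonal NPP
dynamics, or the real basin's class proportions beyond the qualitative
bands above. Passing structure-recovery tests therefore demonstrates that
the pipeline's machinery is correct and deterministic, not that the
published basin-specific counts would be reproduced from the real data.

An even-sized focal window has no centre cell; the published 36×36 relief
neighbourhood is implemented as the odd 37×37 window (the difference is
one ring of cells). A power-2 inverse-distance-weighting utility is
provided for station data but is not on any tested analysis path.

## Numerical conventions and degenerate inputs

- AHP: power iteration from the uniform vector, relative tolerance 1e−10,
  max 10 000 iterations; reciprocity enforced to 1e−6 (fraction entries are
  parsed as exact rationals, so published matrices are reciprocal to
  machine precision). CI is defined as 0 for n ≤ 2; CR is 0 whenever
  RI(n) = 0; RI is tabulated for n ≤ 10 only.
- Min–max normalization of a constant layer is an error (undefined
  scaling), as is natural-breaks classification with fewer distinct values
  than classes.
- Current conservation in the Laplacian solve is verified to 1e−8 against
  dense solves in tests.
- Checksums (SHA-256 over raw cell bytes plus geometry) recorded in the
  run manifest make end-to-end determinism checkable between runs.

## Problem sizes

Tests and the acceptance checks run at desk scale: oracle comparisons on
≤10×10 surfaces (50 random replicates), dense circuit solves on ≤100-node
networks, exhaustive partition enumeration for n ≤ 12, and full-pipeline
runs on 200×200-cell landscapes (a full run takes a few seconds on one
CPU). These sizes exercise every code path; nothing in the implementation
is specific to them, and the sparse solvers scale to basin-sized rasters.

## Known limitations

- No reprojection: all inputs must already share one grid template.
- Corridors are single least-cost centrelines plus a cost-slack swath;
  multi-path corridor braiding beyond the circuit-theory current map is
  not modelled.
- The published factor-weight table is used as printed even though it is
  not the eigenvector of the published comparison matrix (see Resistance);
  users wanting internal consistency should recompute weights from their
  own matrix.
- Species-specific movement (dispersal kernels, behavioural avoidance) is
  outside the resistance-surface abstraction.
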