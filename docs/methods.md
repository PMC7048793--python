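# Methods

## Scope and model

The package quantifies cortico-cortical connectivity measured with
retrograde tracers: each injection labels the cell bodies of neurons that
project to the injected site, and the labeled cells — registered to a
parcellated 3D template with laminar (supra/infragranular) annotations —
are the raw data.  Three analysis layers sit on top: connectivity matrices
(FLNe/SLN), wiring-cost geodesic distances, and the statistics that relate
them (connectivity-distance regression, local/distant network comparison).

### Connectivity quantification

For an injection into area A, FLNe(B→A) is the count of labeled cells in
B divided by all labeled cells outside A; intrinsic (within-A) cells are
excluded from numerator pool and denominator alike, so each injection's
extrinsic FLNe vector sums to exactly 1.  SLN(B→A) is the supragranular
share of the projection's cells; it is undefined (NaN, never raised) for
zero-count projections and for source areas without a visible layer 4
(`quantify.NO_LAYER4_AREAS` lists the marmoset atlas names: entorhinal and
piriform cortex, the amygdalopiriform transition area, area 29
subdivisions).  Aggregation across repeat injections into one area follows
the field's convention: FLNe is the arithmetic mean **with unobserved
projections counted as 0** — averaging only over observing injections
biases strengths upward; the alternative is available via
`unobserved_as_zero=False` — while SLN is recomputed from supra/infra
counts pooled over the injections in which the projection was observed.
Cells inside an injection's halo exclusion zone stay in FLNe counts when
extrinsic; the known cost is a conservative under-estimate of intrinsic
connectivity, which the matrices do not evaluate anyway.

Matrix display order comes from average-linkage agglomerative clustering
on the correlation distance between log10(FLNe + 1e-6) source profiles.
Linkage and metric are a package choice (log compression reflects the
orders-of-magnitude spread of FLNe; correlation distance compares profile
shape, not magnitude); zero-variance profiles get an infinitesimal ramp so
the correlation distance is defined.

### Wiring-cost geodesics

Tissue classes map to traversal speeds: white matter 1.0, gray matter
0.05, outside 0 (impassable).  Arrival times from a seed solve the Eikonal
equation |∇T| = 1/speed with a first-order upwind Fast Marching scheme on
the (possibly anisotropic) voxel grid.  Numerical choices:

* **Exact-ray initialization.**  Voxels within 3 voxel diagonals of the
  exact seed point that share the seed voxel's speed are initialized with
  their straight-ray time.  This removes the sub-voxel seed-quantization
  error and most of the front-curvature error a first-order scheme accrues
  near a point source (uniform-medium max error 4.3% at 21³, halving under
  grid refinement when the initialization ball is held at fixed physical
  radius).
* **Backtrace.**  Geodesics descend the trilinearly interpolated T in
  fixed steps of ¼ of the smallest voxel edge, stopping within one voxel
  diagonal of the seed (the remaining straight segment is added).  +inf
  values are replaced by a finite ceiling during interpolation, which
  repels paths from impassable voxels.  If the continuous descent stalls
  on a discretization plateau, the walker hops to the lowest-T voxel among
  the 26 neighbors; a walker stuck at a genuine local minimum returns its
  partial length flagged as failed (treated as unreachable upstream).
* **Centroids.**  An area's centroid is the argmax of the signed distance
  transform of its mask — the deepest interior point, guaranteed inside
  the area; ties resolve to the lexicographically smallest voxel index.
* **Bidirectional QC.**  For each pair, tracts are traced in both
  directions and averaged; the discrepancy is |d_fwd − d_rev| / d
  (relative, the package's definition — an absolute-mm variant can be
  derived from the stored d_fwd/d_rev columns).  Unreachable pairs carry
  +inf distance, NaN discrepancy, and are excluded from means.
* **Validation.**  An independent 26-neighbor Dijkstra construction
  (scipy.sparse.csgraph; edge travel time = mean endpoint slowness × edge
  length) cross-checks the solver.  Two caveats bound the achievable
  agreement and are intrinsic to that construction, not solver error: the
  26-neighbor chamfer metric overestimates the Euclidean metric by up to
  ~12% in (2,1,1)-type directions, and at high gray/white contrast the
  mean-endpoint edge weights create a one-voxel-wide artificially fast
  lane along the tissue interface that can flip the route of near-tied
  pairs.  Agreement is therefore tight along lattice directions and in
  channel geometries, and loose (5–15%, occasionally worse on flipped
  routes) elsewhere; the test suite and acceptance script report the
  measured deviations.
* The sweep of mean interareal distance over f_WM/f_GM ratios is monotone
  non-decreasing up to backtrace noise; observed ripple is ~0.03%, and
  monotonicity checks use a 0.5% relative tolerance.

### Connectivity distance and the linear model

Area-based connectivity distance is the cell-count-weighted mean of
centroid distances to the labeled source areas (intrinsic excluded).
Cell-based connectivity distance first projects every cell and the
injection center to the nearest mid-thickness surface point (removing the
laminar-depth bias in distances to white matter; ties break to the lowest
vertex index), drops cells within the injection's exclusion radius of the
projected center (Euclidean, measured after projection, consistent with
the projected geometry), then averages the per-cell tract lengths to the
center — intrinsic and extrinsic cells pooled.  The laminar split applies
the same computation to supra- and infragranular cells separately.

The distance to the nearest primary area is 0 for injections inside a
primary area and otherwise the minimum wiring distance from the barycenter
to any border voxel of a primary area; wiring (not surface) distance keeps
one metric across the package.  Three primary-area sets ship as data
(default sensorimotor; functionally defined sensory; koniocortical).

The regression is ordinary least squares: response (cd_area or cd_cell) on
distance-to-primary plus covariates — location centrality (mean wiring
distance from the injected area's centroid to all other centroids) and
area gray volume; the cell-based variant adds injection volume and the
mean Euclidean distance from the injection center to all gray-matter
voxels (the Euclidean choice keeps the covariate cheap; no metric is
canonical for it).  The slope is reported standardized (all variables
z-scored; the paper-style unitless β) and raw (mm per mm), with the 95% CI,
overall F, and degrees of freedom as computed — df bookkeeping is not
forced to match any external report.  A per-area mode averages records of
injections sharing an area before fitting.  Rank-deficient designs raise.

### Local/distant networks

Per injection, cells within 4 mm of the center (wiring metric by default,
Euclidean selectable) are local, beyond 8 mm distant; intermediate cells
belong to neither class, so the fractions need not sum to 1.  The ratio
local/distant is compared across networks per injection.  Infinite ratios
(no distant cells) are excluded with an audit count; networks with fewer
than 2 usable injections are dropped with a warning.  The omnibus test is
the tie-corrected Kruskal–Wallis H; post-hoc Dunn z-tests on pooled ranks
are Holm-adjusted by default (unadjusted available) and annotated at the
0.05 / 1e-2 / 1e-3 tiers.

## The phantom

The synthetic template is a spherical-shell cortex (default: outer radius
8 mm, thickness 2 mm) over a white-matter core in an 80³ grid at 0.25 mm —
small enough that a Fast Marching solve takes tens of milliseconds, while
keeping ≥ 8 voxels across the cortical thickness.  The shell is
partitioned into contiguous areas by nearest golden-spiral direction
(spherical Voronoi sectors); the supra/infra split at the radial midpoint
stands in for layer 4 and is recorded as a label, not inferred; the
mid-thickness surface is the set of gray voxel centers straddling the
mid radius.  Geometry is deterministic given the config.

Injections are placed at seeded-random gray voxels of requested areas,
with the assigned area re-read from the barycenter voxel and exclusion
radii drawn uniformly from 0.1–1.1 mm (the range reported for injection
halos in retrograde tracer material; deposit core radius is half the
exclusion radius).  Cell tables are multinomial draws per injection: the
expected count in source B for an injection into A is proportional to
pair_weights[A,B] · exp(−d(A,B)/λ) · V_B, with d the **wiring** distance
(generator and analysis share one metric), λ = 3 mm by default, V_B the
source's gray volume (cells fall uniformly in source gray matter, so
counts scale with volume), and intrinsic_weight · V_A for the intrinsic
compartment.  Pair weights default to log-normal (σ = 1) draws — a
heavy-tailed spread standing in for the orders-of-magnitude range of real
projection strengths, whose empirical distribution the generator does not
claim to match.  Each cell is supragranular with the per-pair probability
(default 0.5) and is placed in the matching laminar compartment, so the
positional laminar label always agrees with the attribute.

What the phantom does not emulate: gyral/sulcal morphology, histological
sectioning and registration error, realistic area shapes and adjacencies,
anisotropic template plates, and any planted relation between laminar
origin and distance (supra and infra follow the same spatial law, so the
laminar length ratio is ~1 by construction).  Passing tests therefore
establish the correctness of the computations and the recoverability of
planted structure, not biological fidelity of the numbers.

## Problem sizes and defaults

Tests and the acceptance script run phantoms between 30³ and 80³ voxels
with 4–8 areas and 300–20 000 cells per injection — sizes chosen so the
statistical checks (χ² goodness of fit, z-tests at α = 0.01, 5% recovery
tolerances) have the power they claim while a full suite completes in
minutes on one CPU.  Monte-Carlo calibrations use 500 regression
replicates at n = 143 and 1000 Kruskal–Wallis replicates at five groups of
25–35.  The Kruskal–Wallis χ² reference is slightly conservative at those
group sizes (true size ≈ 4.5%), so calibration windows are nominal ± 2
percentage points.

## Known limitations

* Arrival times are first-order accurate; diagonal errors of a few percent
  remain at coarse resolution (the exact-ray initialization suppresses the
  near-source part only).
* Geodesic lengths inherit backtrace step/stop tolerances (~1 voxel); the
  direction-discrepancy QC is the intended guard.
* The GLM is ordinary least squares: no spatial autocorrelation
  correction, no animal-level random effects.
* The exclusion-zone filter assumes a spherical halo; real halos are
  irregular.
* `io.read_label_volume` accepts any integer NIfTI but the phantom writer
  emits axis-aligned affines only; oblique affines are honored for
  coordinate mapping yet untested against real oblique templates.
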