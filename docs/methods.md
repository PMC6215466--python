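# Methods

This note documents the models, parameter choices and numerical
decisions behind `arealmap`, in the order the pipeline runs. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Surface substrate

All computation happens on a triangulated sphere (subdivided
icosahedron) rather than a brain-shaped surface. Every operation in the
pipeline depends only on mesh topology, edge-length geodesics and the
spherical registration coordinates, and a true sphere makes the
rotation (spin-test) null exact rather than approximate. A polar cap
(default 25° angular radius, ~5% of vertices) is marked as medial wall
so that every stage's invalid-data handling — including the null
model's wall-substitution rule — is exercised.

**Mesh radius (default 25 mm).** The desk-scale mesh (subdivisions = 4,
2562 vertices) carries 40 planted parcels. At radius 25 mm each parcel
covers ≈ 180 mm², matching the areal scale of real cortical parcels
(≈ 90 000 mm² of hemisphere cortex over ~500 parcels). This matters
because several method parameters are expressed in millimetres — 6 mm
FWHM gradient smoothing, 3 mm seed merging, 20 mm centroid exclusion —
and their strength *relative to parcel size* should be the same at desk
scale as on a full-resolution surface. Geodesic distances are shortest
paths over mesh edges (Dijkstra), adequate at these smoothing radii.

## Synthetic cohorts

Per subject, the vertex×frame matrix is

    y_v(t) = s_{sys(p_v)}(t) + u_{p_v}(t) + σ ε_v(t)

with system latents `s`, parcel latents `u` (both white noise band-pass
filtered to 0.009–0.08 Hz at TR = 2 s and z-scored, so preprocessing is
near-idempotent on clean data) and white vertex noise (σ = 1 by
default). With unit amplitudes this yields within-parcel r = 2/3,
within-system/between-parcel r = 1/3 and ≈ 0 between systems — the
ordering the boundary-mapping method assumes.

Two knobs emulate aging effects:

* **Border jitter (`jitter_mm`).** Each vertex within reach of a planted
  border flips to the neighbouring parcel with probability
  `bias(v) · exp(−d/jitter_mm)`, where `d` is the half-gap between the
  nearest and second-nearest parcel seeds (a cheap distance-to-border
  proxy) and `bias` is a smooth cohort-level field in (0.1, 0.9) drawn
  once per cohort. The bias term is essential: purely subject-level
  symmetric jitter only *blurs* cohort-average borders (more
  medium-probability transition vertices) but cannot *displace* them,
  so cohort parcellations would never diverge. With the bias field,
  borders shift cohort-consistently and blur subject-wise — both
  effects.
* **Between-system coupling (`between_system_coupling`, c).** Each
  parcel's system signal is `√(1−c)·s_own + √c·Σ_q √(w_pq)·s_q` with a
  parcel-specific Dirichlet weight profile `w_p` over foreign systems.
  Two rejected alternatives motivated this form: a single shared latent
  is almost entirely removed by global-signal regression (the planted
  desegregation would vanish in preprocessing), and a single fixed
  partner system per parcel creates an *alternative clusterable
  structure* that community detection happily re-partitions, leaving
  segregation relative to detected communities unchanged. Diffuse
  parcel-specific mixing raises between-system connectivity without
  either artefact; it is the package's rendering of age-related system
  de-differentiation.

Motion traces are slow random walks plus Poisson spikes (one-frame
pulses of 0.4–0.8 mm). Spikes inject an artifact with a near-global
component (removable by global-signal regression) *and* a strong
vertex-random component (removable only by scrubbing the frame) —
without the heterogeneous part, scrubbing would have no measurable
benefit after regression, which is neither realistic nor testable.
Thickness maps thin with age, concentrated in association-system
parcels and near borders; deformation maps co-vary with the cohort's
border-displacement field, so that between-cohort boundary differences
are genuinely mediated by between-cohort structural differences (the
association the boundary-difference regression must recover).

Default cohort: 20 subjects, 200 frames, TR 2 s, jitter 1 mm, coupling
0.1, spike rate 0.02/frame. The lifespan design uses five cohorts
(20–93 y) with jitter 0.75→4.5 mm and coupling 0.03→0.25.

## Preprocessing

Two iterations, each residualising (OLS with intercept; motion, global
signal over cortex, and first-difference derivative terms) and then
band-pass filtering (order-2 Butterworth, zero-phase `filtfilt`,
0.009–0.08 Hz). Iteration 1 runs on all frames, motivating the ±1-frame
pad around FD > 0.3 mm flags (temporal spread of artifact through the
filter); iteration 2 re-runs on retained frames only, filtering the
concatenated retained series (simple, with a documented bias at
censoring joins, rather than spectral interpolation). The rotational FD
components use a 50 mm conversion radius — the convention of the FD
definition — configurable. Subjects under 75 retained frames are
flagged unusable, never silently dropped.

## Boundary mapping

Connectivity uses the full signed correlation distribution, Fisher
transformed with r clipped to ±(1−10⁻⁷). In the RSFC similarity matrix,
entry (i, j) correlates rows i and j of the cohort-mean z-matrix with
the two self-connection entries (columns i and j) excluded from both
rows — their clipped-ceiling values would otherwise inflate every
similarity. The computation is blockwise (full-row sums plus per-pair
correction terms), keeping the working set O(V·block).

Per column of the similarity matrix: tangent-plane least-squares
gradient magnitude (a linear fit of the map over each vertex's 1-ring
in local tangent coordinates; exact on constants, analytic on linear
fields restricted to the sphere), then 6 mm FWHM geodesic Gaussian
smoothing (kernel truncated at 3σ, renormalised over valid
neighbours). Gradient-then-smooth order follows the method's step
listing. The watershed on each column floods from plateau-collapsed
local minima in (value, vertex index) order; a vertex reached by two
basins becomes a ridge. Ridge images are binary; their average over all
valid seed columns is the boundary map. Flooding depends only on the
rank order of values, so the whole chain is invariant to global scaling
of the input time series.

## Parcellation

"Threshold 35%" is read as the 35th percentile of the boundary-value
distribution acting as a flooding ceiling — resolution-independent, and
configurable because the alternative readings (fraction of range,
absolute probability) cannot be excluded. Note a structural consequence
of this reading: the number of parcels *grows* with the threshold
(higher ceilings admit more seed minima and basins never merge), so
"over-segmentation at low thresholds" in the ridge-saliency sense does
not apply to this variant; the sweep test asserts the monotonicity the
ceiling semantics actually implies.

Two desk-resolution compensations, both off by default in the library
function and enabled in the pipeline:

* **Seed merging** (default radius = 3 mean edge lengths, ≥ 3 mm, i.e.
  ≈ 3 mm on a 32k cortical mesh): minima within the radius of a
  stronger minimum are dropped. A boundary map is an average of binary
  images; at 2.5k vertices it fluctuates at the single-vertex scale and
  every noise bump below the ceiling would otherwise seed a
  micro-parcel.
* **Boundary-map presmoothing** (`presmooth_fwhm_mm`, pipeline default
  6 mm — the gradient-smoothing kernel): repairs the same fluctuation
  at the map level. Diagnostically, without it the derived parcellation
  at desk scale had ~55 parcels for 40 planted ones with *perfect*
  member purity — every excess parcel was a fragment of a planted
  parcel's interior split by a noise bump. At 32k the binary average is
  intrinsically smooth and the default of 0 reproduces the plain
  method.

Single-vertex parcels are dissolved (no homogeneity PCA is possible on
them); basins are restricted to the connected component holding their
seed; labels are assigned in seed-vertex order, making runs bitwise
reproducible.

## Rotation nulls

One engine serves every Z score: the payload (map or labelling) is
rotated by n seeded uniform rotations (uniform quaternions),
nearest-neighbour resampled on the sphere coordinates (label-safe; also
used for scalars, for consistency), and the statistic recomputed per
rotation; Z = (actual − null mean)/null SD, with a ±∞ sentinel when the
null is degenerate. Per-unit invalidity under rotation — a vertex
landing on the medial wall, or a parcel losing more than 25% of its
members to it — is repaired by substituting that unit's mean over the
valid rotations before aggregation, so wall clipping does not bias the
null. Nearest-neighbour resampling is many-to-one: a rotate/rotate-back
round trip restores ~90% of vertices exactly (the composed rotation
restores all of them), and clipped rotations bias rotated-parcel sizes
low unless excluded — both properties are asserted in the tests at the
levels the resampling actually attains.

## Evaluation statistics

* **Homogeneity**: PCA with whole-surface target vertices as
  observations and parcel members as variables (each member map centred
  over targets); the PC1 eigenvalue share of the member covariance,
  × 100. Invariant to global shifts and scaling. All target columns are
  retained (including own-parcel targets); the choice is benign at desk
  scale and configurable.
* **Silhouette**: dissimilarity 1 − r between whole-surface maps;
  `a_i` over own-parcel members, `b_i` pooled over all members of all
  immediately adjacent parcels (not the classic per-cluster minimum).
  Adjacency bridges unassigned zones by attributing each unassigned
  cortex vertex to its geodesically nearest parcel; parcels whose
  extended territories share an edge are adjacent. With thin ridges
  this reduces to ordinary adjacency; with wide above-ceiling zones it
  keeps every parcel comparable.
* **Matching**: each parcel of A matches its maximal-Jaccard parcel of
  B (ties to the lower label; multiple A→same B allowed). Matched-pair
  RSFC similarity correlates the parcels' cohort-average connectivity
  maps.
* **ARI**: pair-counting adjusted Rand index over vertices assigned in
  *both* labellings. A desk-scale caveat: parcels cover ~35% of the
  cortex under the ceiling semantics, so displaced borders mostly turn
  into exclusions rather than disagreements, making ARI a much less
  age-sensitive comparison than boundary Dice at this scale; the
  aging analyses therefore lean on Dice/map correlation for strict
  monotonicity and on ARI for the coarser youngest-vs-oldest contrast.
* **Task dispersion**: within-parcel SD of beta values averaged over
  conditions then parcels, with a lower-tail spin null (aligned
  parcellations yield smaller SD than rotated ones).
* **Boundary-difference regression**: OLS of |Δboundary| on
  |Δthickness| + |Δdeformation| (optional interaction) over valid
  vertices, with overall F and per-predictor t. The null calibration
  check draws the response as white noise — under spatially smooth
  responses OLS p-values on vertex data are anti-conservative, which is
  a property of mass-univariate regression generally, not of this
  implementation.
* **Summary ANOVA**: F from printed group means/SDs/Ns
  (SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sdᵢ²). The worked example uses a
  published lifespan cohort MMSE table; rounding of the printed
  summaries dominates the residual difference from the published F.
* No multiple-testing correction is applied within the evaluation
  module; rotation-null p values are reported raw.

## Network analysis

Nodes are parcels (mean member series), edges Fisher-z correlations;
negative edges are retained in the matrix but excluded from
thresholding and from segregation means; node pairs with centroids
closer than 20 mm (Euclidean, anatomical coordinates) carry no edge at
any density. Density thresholding keeps the top round(d·n(n−1)/2)
candidate edges with deterministic tie-breaking; edge sets are nested
across densities.

Community detection is a native two-level map-equation minimiser:
greedy best-improvement single-node moves to convergence, restarted
from the singleton partition, the one-module partition and random
partitions (best codelength kept; seeded, deterministic). Implementing
it natively (rather than binding an external program) buys seeded
determinism and lets the test suite verify global optimality against
exhaustive partition enumeration on ≤ 8-node graphs. Bootstrap mode
consensus aligns each bootstrap partition to the first by
maximal-Jaccard label matching before taking per-node modes — a mode
over raw labels would be ill-defined across runs. The cross-density
consensus dissolves communities below the minimum size (default 6
nodes) or present at a single density; dissolved nodes take their
assignment at the nearest denser threshold where their community is
valid, then a majority-across-densities rule — a codified, logged
replacement for the manual reassignment step such analyses otherwise
need.

Segregation: overall scope uses pooled means over within- and
between-system positive edges; typed scopes (association,
sensory-motor, association-to-sensory) average per-system means, per
the type-wise definitions. Note that with finite data the
positive-edge-only rule leaves a truncated-noise floor in Z̄b, so
segregation sits below 1 even for exactly uncorrelated systems. Age
trends report Pearson r and a cubic polynomial OLS F(3, N−4) on
standardised age.

## Problem sizes used in tests and acceptance

* Full desk scale (planted-structure recovery): 2562 vertices, 40
  parcels, 5 systems, 20 subjects × 200 frames, 6 boundary bootstraps,
  100-rotation nulls, 20 network bootstraps over densities
  {3, 5, 7, 10}%.
* Lifespan design: 642 vertices, 24 parcels, 4 systems, 5 cohorts × 10
  subjects × 150 frames, aggregated over 10 seeded replicates. At this
  node count the full-scale minimum community size (6) would dissolve
  entire planted systems and the 20 mm exclusion would remove ~30% of
  node pairs, so both are scaled with the mesh (minimum size 4,
  exclusion 14.4 mm = 20 mm × 18/25). Directional claims are asserted
  on replicate means (boundary similarity decline), pooled subjects
  (segregation–age correlation, n = 500) and sign tests across
  replicates × cohorts (cohort-specific vs young-parcellation fit),
  which is also how the single-replicate Monte Carlo noise (each
  effect holds in ~80% of single runs) is controlled.
* The library defaults remain the full-scale values (100 boundary
  bootstraps, 1000 network bootstraps, 100 rotations, minimum
  community size 6, 20 mm exclusion).

## Known limitations

* The sphere has no folding, no hemispheric pair, and no
  anatomically realistic medial wall; contralateral connectivity
  (32k × 64k correlation maps in real data) collapses onto the single
  surface.
* The generator's aging parameterisation (jitter, coupling) is this
  package's own; the literature documents *that* borders blur and
  systems desegregate with age, not a quantitative generative model.
* Nearest-neighbour rotation resampling is label-safe but not
  area-preserving at the single-vertex level.
* Passing recovery tests on synthetic cohorts shows the chain is
  implemented correctly and sensitive under its own generative
  assumptions (block structure, stationary band-limited signals,
  additive spikes); it does not certify performance on real BOLD data
  with spatially structured noise, hemodynamic variability, or
  registration error.
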