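# Methods

## Coordinate conventions

Voxel indices are 0-based; world coordinates are millimetres through the
4×4 voxel-to-world affine. A world point belongs to the voxel
`floor(A⁻¹p + 0.5)` (nearest-voxel rule). Streamlines and meshes live in
world mm everywhere; no stage re-interprets coordinates.

## Tensor phantoms

Bundles are tubes of radius `radius_mm` around a parametric centerline
(straight segment, circular arc, or polyline). A voxel whose centre lies
within the radius of the *sampled* centerline (sample spacing = min voxel
edge / 4) carries an axially symmetric tensor with eigenvalues (a, r, r)
and principal eigenvector equal to the centerline tangent at the nearest
sample. For a target FA at fixed mean diffusivity MD (default
0.7 × 10⁻³ mm²/s, a typical white-matter value), the closed form

δ = FA / √(3 − 2 FA²),  a = MD(1 + 2δ),  r = MD(1 − δ)

gives FA exactly (for (a, r, r), FA = (a − r)/√(a² + 2r²)). Background
voxels get the same construction at `background_fa` (default 0.05) with a
seeded random orientation. Because membership is distance to the
*centerline*, straight bundles acquire spherical end caps: an 80-mm bundle
of radius 4 mm supports streamlines up to ≈ 88 mm. Overlapping bundles
resolve to the nearest centerline (with a warning). Eigenvalue noise
(`noise_sd`, multiplicative Gaussian) re-sorts eigenvalues and their frames
after perturbation.

Tensors are stored as eigen-decompositions (3 eigenvalues + orthonormal
frame), which makes FA and principal-direction queries exact; converters
to/from the 6-component lower-triangular symmetric form handle NIfTI I/O.

## Sphere surfaces

`make_sphere_surface(n, r)` places a Fibonacci lattice of exactly *n*
points on the sphere and triangulates by convex hull (every lattice point
is in convex position), flipping faces to outward orientation. This yields
a closed genus-0 2-manifold (Euler characteristic 2) at *any* requested
vertex count — icosphere subdivision can only produce counts
12, 42, 162, …, so it cannot honour arbitrary sizes. No cortical folding
is simulated; the pipeline's math is geometry-agnostic.

## Parcellation (k-medoids)

Distance is the graph geodesic along mesh edges (Dijkstra) — it respects
surface topology, unlike Euclidean chords. Seeding: the RNG picks the
first medoid; the rest follow by deterministic farthest-point (maximin)
selection. Each iteration assigns every vertex to its nearest medoid
(ties broken by lower CU id), evaluates the exact full-graph objective,
then re-selects each cluster's medoid using geodesics on the cluster's
induced subgraph (clusters are small contiguous patches, so the subgraph
restriction is cheap and almost always exact). If the objective ever
fails to decrease, the offending update is discarded and iteration stops,
so the recorded objective sequence is strictly decreasing and the
parcellation is bit-reproducible per seed. Default K = 2000.

**CU volume.** A surface patch has no intrinsic volume; the CU's voxel
mask is the set of voxels intersected by the patch swept inward along
interpolated vertex normals by `thickness_mm` (default 2 mm, matching a
typical DTI slice thickness). Faces are sampled at half-voxel density and
each sample attributed to the CU of its nearest face vertex, so masks of
adjacent CUs overlap only along borders. Note that "every intersected
voxel" systematically overcounts a thin shell by up to a voxel layer per
side — the count (and therefore V_CU) depends on grid resolution. This is
accepted: FiCD compares like against like within one grid, and the volume
normalisation is what corrects CU-size inhomogeneity. An empty mask
(possible on very coarse grids) falls back to the medoid's voxel, with a
warning.

## Deterministic tracking

FACT-like fixed-step Euler integration: step 1.0 mm (half a typical 2-mm
voxel), direction = trilinearly interpolated principal eigenvector with
per-corner sign alignment to the incoming direction (tensor eigenvectors
have no intrinsic sign), renormalised. A step is refused when interpolated
FA at the new point is < 0.14, the turning angle between consecutive steps
exceeds 45°, or the point leaves the field of view. Streamlines grow
bidirectionally from each seed; the backward march starts against the
*first forward step* so the junction angle also obeys the threshold.
Growth stops once total length reaches 300 mm (the streamline is kept,
truncated; the forward direction is grown first and the backward march
receives the remaining budget). Streamlines shorter than 30 mm are
discarded. Seeds are jittered uniformly within every voxel at or above the
FA threshold (1 per voxel by default); the RNG is used only for jitter, so
a fixed seed reproduces the tractogram bit-exactly. Every tracking call
re-validates the contract (min FA, max turn, length bounds) on its output.

A streamline's **mean anisotropy (MA)** is the arithmetic mean of FA
trilinearly interpolated at its points; the anisotropy index is FA.

## FiCD maps

A streamline is an *association fiber* of a CU when at least one endpoint
rasterises into the CU's voxel mask — termination at the interface, not
traversal, which would double-count passing fibers. A streamline with both
endpoints in one CU counts once; endpoints in two CUs contribute to each.
FiCD(CU) = ΣMA / V_CU, zero when no fibers connect. Per-CU values are
projected to the vertices (constant within a CU). The **global FiCD** is
the unweighted mean over CUs; an area-weighted variant is available via
`global_ficd(..., area_weights=...)`. Group space is the shared template
mesh (identity registration for synthetic cohorts); a per-vertex
correspondence hook can be supplied for externally registered data.

## Surface smoothing

Explicit discrete heat diffusion `x ← x − dt·A⁻¹Lx` with the
uniform-weight graph Laplacian L and barycentric vertex areas A. Because
`1ᵀL = 0`, the area-weighted mean is conserved exactly, and the operator
is linear. The time step is 0.2·min(aᵢ/dᵢ) — well inside the stability
bound, small enough that the iteration count gives fine control of the
kernel width. The iteration count for a requested FWHM is calibrated per
(mesh, FWHM): a unit impulse is diffused and its geodesic FWHM measured
(binned radial profile, linear interpolation at half maximum) until the
target is bracketed; the calibration is cached on the mesh. Measured
impulse FWHM is within 1% of the 10-mm request on spheres of 2562–40962
vertices. A request below the mean edge length cannot be honoured and
returns the input unchanged with a warning.

## Vertex-wise inference

Per-vertex OLS with group indicators plus covariates; t statistic for the
contrast, two-sided p (exact-fit vertices get t = 0). Clusters are
contiguous vertices with p < 0.01 (two-sided); extent is the summed
barycentric vertex area in mm². The Monte Carlo null synthesises
iid-Gaussian vertex maps, smooths them, standardises, thresholds at the
same two-sided p-level (normal quantile), and records the maximal cluster
extent per iteration (default 10 000 iterations); an observed cluster's
corrected p is the fraction of null maxima at least as large.

**Null smoothness.** Matching the null to the *applied* kernel FWHM is
wrong whenever the data have intrinsic spatial structure: FiCD maps are
piecewise-constant over CUs before smoothing, so their residual field is
smoother than the kernel, and a 10-mm null then inflates the family-wise
error drastically (measured ≈ 0.48). The correction therefore takes the
smoothness to simulate as a parameter, and the pipeline estimates it from
the GLM residuals: the mean vertex–vertex correlation is inverted through
the Gaussian autocorrelation exp(−d²/4s²), first at the mean edge lag and
then refined by a through-origin fit of −log ρ against d² over geodesic
lags out to one FWHM — the scale that governs threshold-excursion extents.
Fitting only the shortest lag underestimates smoothness (measured FWER
0.087), fitting far lags overestimates it (0.027); the one-FWHM window
gives 0.043 against the nominal 0.05 (300 null replicates). This mirrors
what surface-based neuroimaging packages do when they estimate residual
smoothness before their own Monte Carlo simulations.

## Cohort statistics

* Reduction ratio: 100 · (control mean − group mean) / control mean.
* Regional FiCD: unweighted CU mean over an ROI.
* Cognitive scores are z-transformed over all subjects pooled (sample sd).
* Partial Pearson correlation by residualisation: x and y are regressed on
  the covariates, the residuals correlated; p from the t transform with
  n − k − 2 df. (Equivalent to the precision-matrix formula; verified in
  tests against pingouin.)
* Global-FiCD regressions: simple regressions on lacune volume, log-WMH
  volume (natural log; zero volumes offset by 0.001 ml ≈ one 1-mm voxel),
  relative brain volume, age, sex.
* One-way ANOVA with Bonferroni (pooled-variance pairwise t, p × m) and
  Tamhane-T2 (Welch pairwise t, Šidák adjustment 1 − (1 − p)^m) post hocs;
  no ready-made Tamhane-T2 exists in the scientific Python stack, so it is
  implemented here from its definition.

## Synthetic cohorts

Group sizes default to (35, 34, 22) — control, CSVD with normal cognition,
CSVD with MCI — matching the study design this pipeline targets. Subject
maps are template × group-specific regional reduction factors ×
multiplicative log-normal noise per CU (σ = 0.1; multiplicative noise
keeps maps nonnegative). Covariates: age ~ N(63.5, 6.7²) years, sex ~
Bernoulli(0.6 male), education ~ round(N(9, 3.5²)) years — cosmetic
matching of a typical elderly CSVD sample. Lesion burdens are log-normal
with group-ordered medians (WMH 0.5/6/13 ml; lacunes 0/0.25/0.7 ml;
relative brain volume 0.80/0.79/0.77 ± 0.025), chosen so patient groups
order as real cohorts do. Cognitive scores are a linear function of
regional FiCD plus Gaussian noise.

What the generator does **not** emulate: cortical folding and
registration error (all subjects share one sphere), crossing fibers and
partial-volume tensors, spatially structured lesion topography coupled to
the fiber anatomy, and any direct mechanistic link between lesion volume
and FiCD (group membership induces their correlation). Passing tests
therefore demonstrate the pipeline's internal correctness and statistical
calibration under a known generative model — not clinical
reproducibility, which requires real data.

## Problem sizes and runtime choices

The test suite runs the parcellation contract at full study scale
(20480 vertices, K = 2000; ≈ 45 s) and the statistical calibration at
500 null cohorts × 500 Monte Carlo iterations on a 2562-vertex sphere
(≈ 3 min) — the sphere is sized so the 10-mm kernel spans many edge
lengths while the full suite stays in the minutes range. The acceptance
script uses a 40962-vertex sphere for the smoothing measurement and
full-volume seeding for all tracking phantoms. Cluster-correction
defaults remain at the production 10 000 iterations; experiments pass
reduced counts explicitly.

## Interfaces

The library is the interface: the numbered drivers under `analysis/`
compose it the way a study would, and all formats go through `ficd.io`
(NIfTI volumes, TCK tractograms, ASCII OFF meshes with optional GIFTI
export, TSV tables, TOML config). No console-script CLI is installed —
every documented operation is a plain function call, and the drivers are
runnable scripts.

## Known limitations

Deterministic single-tensor tracking cannot resolve crossing or kissing
fibers; the k-medoids subgraph medoid update is a heuristic (guarded by
the monotone-objective stop); CU volumes are resolution-dependent by
construction (see above); the Monte Carlo null assumes a
Gaussian-autocorrelation field summarised by one FWHM; and Tamhane's T2
uses the Šidák bound rather than the exact studentised distribution.
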