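# Methods

This note documents the models, conventions and numerical choices behind
`fishmorph`, and what the synthetic data generator does and does not
emulate.

## Coordinate and orientation conventions

All geometry uses the mathematical convention: y up, closed polygons
counter-clockwise (interior on the left), the closing edge implicit.
Image-derived inputs (PNG masks, landmark files digitised in image
coordinates) are flipped to y-up on ingestion. Outlines carry five named
anchors as vertex indices, met in the order snout tip → pelvic origin →
ventral caudal-fin base → dorsal caudal-fin base → dorsal-fin origin when
traversing CCW from the snout.

## Mask → outline

The boundary of the largest 8-connected foreground component is traced as a
*crack boundary*: edges between foreground and background pixel cells at the
0.5 threshold, chained with the foreground on the left. For a hole-free
4-connected blob the shoelace area of the traced polygon therefore equals
the foreground pixel count exactly; this is the property the unit tests pin.
Two caveats are inherent to the definition: interior holes are ignored (the
outer loop is the one with the largest positive area), and a blob pinched at
a diagonal 8-connection cannot be bounded by one simple polygon — the trace
resolves pinch vertices by the left-most turn, which can drop pinched-off
pixels (observed effect on rasterised fish: ~2 pixels in 10⁴). Component
ties are broken by the smallest (row, column) of the topmost-leftmost pixel.

Resampling places exactly *n* vertices at equal arc length, starting from
the snout-tip anchor; anchors are re-snapped to the nearest new vertex and
the strict anchor ordering is re-validated.

## Superimposition

**Full GPA** (landmarks): each configuration is centred and scaled to unit
centroid size once; the consensus is initialised to the first configuration
and updated by (i) rotating every configuration onto it with the optimal
*proper* rotation (SVD with determinant correction — reflections are never
applied, because all specimens face the same way; a configuration whose
unconstrained optimum is a reflection triggers a warning instead), and
(ii) recomputing, centring and unit-scaling the mean. Iteration stops when
the Frobenius change of the consensus falls below 1e-10 (max 100 rounds;
convergence for 12 landmarks is typically 2–3 rounds). The residual is the
summed squared deviation of the aligned configurations from the final
consensus. For two configurations this residual relates to the full
Procrustes distance d (itself verified against a rotation-angle grid search
at 1e-4 rad) by residual = 4 − 2·sqrt(4 − d²), a consequence of the
unit-scaled consensus; the test suite asserts this exact relation.

**Anchor alignment** (outlines): the population reference is a mini-GPA
consensus of the five-anchor configurations; each outline is then mapped by
the least-squares similarity transform (translation, isotropic scale,
rotation; no reflection — Umeyama with the reflection branch disabled)
estimated on its anchors only and applied to every vertex. Aligning on
anchors rather than the full contour keeps the alignment anchored to
homologous features and is deliberately inexact for the rest of the contour.

## Elliptic Fourier analysis

Coefficients follow Kuhl & Giardina's closed form for a polygon
parameterised by cumulative chord length: for harmonic h,
a_h = T/(2h²π²) Σ_p Δx_p/Δt_p [cos(2πh t_p/T) − cos(2πh t_{p−1}/T)], and
likewise b (sin/x), c (cos/y), d (sin/y). The positional constants A0/C0
are excluded throughout; inverse reconstruction is centred at the origin.
No post-hoc first-ellipse normalisation is applied: orientation, scale and
start point are already standardised by the anchor Procrustes step and the
snout-tip start convention, and renormalising would discard real rotational
differences the anchors preserve.

Two numerical facts worth knowing. First, coefficients of a sampled curve
converge at O(n⁻²) in the sampling density, so "analytic" expectations only
hold to ~1e-3 at 256–512 points (the tests budget for this). Second, the
chord-length parameter is *not* the ellipse angle: a (4, 2) ellipse has
a1 ≈ 3.65668, d1 ≈ 2.14591 under arc-length parameterisation, not (4, 2).
The implementation is verified against dense trapezoidal integration of the
defining integrals (10⁵ substeps, agreement ≤ 1e-6).

Harmonic power is P_h = (a_h²+b_h²+c_h²+d_h²)/2. The truncation order H*
is the smallest H whose cumulative power fraction — evaluated against a
full decomposition at H_max = 32, averaged over the collection (or the
worst shape with `per_shape=True`; which of the two a study means by "99%
cumulative power" is rarely stated, so both are exposed) — reaches the
threshold (default 0.99). The OA feature matrix uses harmonics 1..H*
(4·H* variables). Synthetic outlines are smoother than real digitised fish,
so H* ≈ 4 here where photograph-derived datasets typically need ~15.

## Trait catalog

The 13 default traits are widely used diet-and-locomotion ratios over a
schema of 17 lengths and 3 areas (eye size, eye position, oral gape
position, elongation, head length ratio, caudal peduncle throttling, caudal
fin aspect ratio, pectoral fin position and aspect ratio, dorsal spine
ratio, body surface ratio, pectoral and caudal fin surface ratios). Every
default trait is homogeneous of degree zero under (lengths × c,
areas × c²), which the property tests exploit. The catalog is data — an
ordered (name, numerator, denominator) table with a safe expression grammar
(+, *, integer **) — so a different study's trait set is a CSV edit. No log
transform or allometric correction is applied by default.

## Morphospaces

One PCA per approach via SVD of the centred (TM: z-scored; LA/OA:
covariance-only, standard geometric-morphometric practice) feature matrix;
three axes retained for an even comparison across approaches. Explained
fractions are of the *total* variance. Axis signs follow a deterministic
convention (largest-magnitude loading positive); cross-approach Pearson
correlations are sign-aware and therefore document the convention — the
congruence statements in the tests use |r|. Reconstruction along an axis is
mean_form + score × loading (× per-variable std for standardized spaces),
reshaped to landmarks for LA or inverted through the truncated Fourier sum
for OA.

## Group differentiation

Silhouette widths use the Rousseeuw definition on Euclidean distances over
the retained axes; singleton-group members and the degenerate a = b = 0
case get s = 0. The overall statistic for a grouping is the mean of s over
individuals (one number per scheme × approach). Significance comes from a
species-level permutation null: the species → group map is permuted
(preserving group sizes among species) and propagated to individuals, so
conspecifics always share a null label and the within-species correlation
structure is respected. The p-value is one-sided (greater) with the
add-one correction, p = (1 + #{null ≥ observed})/(1 + B); B defaults to
1000-scale and is rejected below 99. Families of tests run in one
`differentiation_table` call (all scheme × approach combinations) are
adjusted together with Benjamini–Yekutieli FDR (delegated to statsmodels;
verified against the hand step-up formula).

## Community diversity

Species scores are unweighted means of individual scores (occurrence data
are presence/absence, so no abundance weighting anywhere). Richness of a
site is 100 × (convex-hull volume of its species) / (hull volume of the
full species pool) — the pool denominator makes 100% attainable and sites
comparable. A site with fewer than four affinely independent species has no
3-D hull; its richness is reported as missing with a warning, never as
zero, and missing sites drop out of downstream tests pairwise. Dispersion
is the mean Euclidean distance of present species from their centroid.

Rank congruence between approaches is Spearman's ρ with average ranks for
ties; the two-sided p is an exact permutation probability for ≤ 8 sites
(8! enumerations) and the t-approximation above — study designs of ~12
sites sit in the approximation regime either way. Exposure comparisons are
one-way ANOVAs (one per index per approach, 6 tests by default, Bonferroni
threshold 0.05/6), each with Shapiro–Wilk on residuals and a
residual-vs-fitted table for homoscedasticity inspection; Tukey HSD
pairwise comparisons accompany the report.

## Synthetic data generator

The generator produces what a digitised lateral-view photo collection
provides — outline + anchors, 12 landmarks, 17+3 measurements, optionally a
rasterised mask — from one parametric body plan, so the three pipelines see
mutually consistent views of the same individual. With standard length 1
and body depth D = 1/E, the half-depth profile is
(D/2)·rise(s)·taper(s) + fin bumps: rise climbs from a pointed snout to 1
at s = 0.42 (reaching `head_depth_ratio` at the end of the head), taper
descends smoothly to `peduncle_width_ratio` at the caudal base, and dorsal
(s ∈ [0.50, 0.80]) and anal fins are sine² bumps whose supports avoid the
deepest station — so the measured body depth is exactly D and trait
recovery is exact at zero noise. A forked caudal fin (length, depth, fork
parameters) closes the contour. Landmarks and anchors sit at analytically
known loci; measurements come from the same closed forms (areas by dense
quadrature of the analytic profiles).

Noise is Gaussian displacement along the local outward normal, smoothed
circularly along the contour with a Gaussian kernel of width 5% of the
perimeter (real outline noise is spatially correlated; uncorrelated jitter
would produce non-physical jaggedness and unrealistically heavy high
harmonics). Displacement is capped at 40% of each vertex's clearance — its
distance to the nearest non-neighbouring vertex — so the two sides of thin
caudal-fin lobes cannot cross; in the rare case a draw still
self-intersects, the amplitude is halved and redrawn (deterministically,
from the same generator). Landmarks and measurements receive jitter of the
same scale (additive and multiplicative respectively), mimicking
digitisation error.

Assemblages nest individuals in species (between-species SD 0.06 of each
parameter's range; within-species 0.02) in genera in groups; group effects
are parameter shifts scaled by a single effect size δ, concentrated on
elongation and secondarily on head and peduncle form — the axes that
dominate real reef-fish variation. Defaults mirror a realistic study:
111 individuals / 40 species / 11 genera / 3 families, outline noise
σ = 0.01·SL, and a 12-site occurrence matrix stratified 4/5/3 across
low/moderate/high wave exposure with per-stratum occupancy (0.75, 0.60,
0.45), redrawn (bounded) until every site hosts ≥ 4 species. Two of the
three feeding-functional schemes are nested in family (carrying
morphological signal); the macroalgae-interaction scheme is assigned at
random (no signal) so the permutation machinery has a true negative.

**What passing tests do and do not show.** The generator's outlines are
smoother, its landmarks cleaner and its group structure more Gaussian than
photographs of real fish; tests on it demonstrate that the pipeline
recovers known structure (elongation as PC1 in all three approaches,
silhouette monotone in δ, calibrated type-I error at δ = 0), not that any
particular real dataset will show the same magnitudes. Quantities tied to
fine outline texture (e.g. the harmonic count at 99% power) are expected to
differ from photograph-derived values.

## Problem sizes and determinism

Default analyses run at the study scale above (a full run of
`scripts/acceptance.py` takes seconds). Statistical calibration tests use
500 replicates at B = 199 permutations; oracle tests use 10⁵-substep
integration, 10⁶-sample Monte-Carlo hulls and 1e-4-rad rotation grids. All
randomness flows through explicitly seeded `numpy` generators passed as
objects; no global state is used, and identical seeds reproduce outputs
bit-for-bit.

## Known limitations

* 2-D lateral view only; no cross-sectional or 3-D shape.
* Anchor/landmark placement on real images is the user's responsibility
  (digitisation is out of scope); automatic anatomical landmarking is not
  attempted.
* No sliding semi-landmarks; outline and landmark information are kept in
  their separate pipelines by design.
* Dispersion is unweighted (presence/absence); abundance-weighted
  functional-diversity indices are out of scope.
* The crack-boundary exactness property assumes hole-free, un-pinched
  blobs; heavily fragmented masks should be cleaned upstream.
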