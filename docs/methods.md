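# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `cropsar` pipeline, in the order data flows through it.

## Dual-pol covariance and conventions

The per-pixel observable is the 2×2 Hermitian covariance of the (VV, VH)
channel pair, stored as three rasters (C11, C22 real; C12 complex).  A
single-look covariance built from a complex channel pair is exactly
rank-1 (C11·C22 = |C12|²); multi-looking (block averaging, truncating
partial blocks) and the 9×9 boxcar filter (element-wise moving average,
reflection padding so the output keeps the input size) average PSD
matrices and therefore preserve positive semi-definiteness.  The
looks-equivalent count is multiplied by the averaging window area; the
9×9 boxcar on single-look data gives 81 effective looks in homogeneous
areas (an over-estimate near field boundaries, where windows mix
classes).  Multi-look factors default to (1, 1): the boxcar dominates the
speckle budget, and exposing the factors as configuration keeps the chain
faithful for users who do multi-look first.

The Stokes view used by the model-based decomposition is

    s1 = C11 + C22,  s2 = C11 − C22,  s3 = 2 Re C12,  s4 = −2 Im C12.

The sign of s4 is a convention; the decomposition uses s3, s4 only
through c = s1²−s2²−s3²−s4², so any self-consistent choice gives the same
mv/ms.  The scene simulator inverts exactly this convention, which makes
generative round trips exact.  Backscatter intensities are reported in dB
with a 10⁻¹⁰ linear floor (numerical safety; far below any simulated
signal).  Whether intensities enter the classifier in dB or linear units
is a free choice; dB is the default because tree ensembles split more
evenly on the compressed scale, and the feature set is configurable.

## Eigen-decomposition (H / A / alpha)

Closed-form eigenvalues of the 2×2 Hermitian matrix, sorted descending
and clipped at zero.  Entropy uses base-2 logarithms (two eigenvalues, so
H ∈ [0, 1] by construction) with 0·log 0 := 0.  Anisotropy is
(λ₁−λ₂)/(λ₁+λ₂) — the only well-defined two-eigenvalue form; quad-pol
formulations written in terms of λ₂, λ₃ do not transfer to dual-pol.  The
per-eigenvector angle is the standard dual-pol pseudo-alpha
α_i = arccos |u_i(1)| (angle away from the first, VV, channel), and the
mean alpha is the pseudo-probability-weighted sum.  Zero-span or
non-finite pixels are flagged degenerate and reported with the
maximum-entropy convention (P = ½/½, H = 1, A = 0, α = 0) rather than
NaN, so downstream stacking never propagates invalid values.  H/A/α are
computed from C2 directly; for dual-pol data the practical convention is
to eigen-decompose the measured covariance, and all reported properties
(ranges, degeneracies) hold for it.

## Model-based volume / polarized decomposition

The Stokes vector is modelled as s = mv·sv + ms·sp with the random-dipole
volume signature sv = [1, +½, 0, 0] (VV first: a random dipole cloud
returns ⟨|VV|²⟩:⟨|VH|²⟩ = 3:1, hence s2/s1 = +½) and a fully polarized
sp.  A noise term n·sn is assumed removed by the speckle filtering and no
estimator for n is implemented.  Because spᵀG sp = 0 for
G = diag(1,−1,−1,−1), mv solves a·mv² + b·mv + c = 0 with a = svᵀG sv =
¾, b = −2(s1 − ½ s2), c = s1²−s2²−s3²−s4²; energy conservation
0 ≤ mv ≤ s1 selects the physical root and ms = s1 − mv.

Root handling (per-pixel diagnostic flags are set in every degenerate
branch):

* both roots admissible (double root or numerical near-tie): the smaller
  root is taken — for any s exactly on the model manifold the true mv is
  always the smaller root, since the spurious root exceeds it by
  2·ms·(svᵀG sp)/a ≥ 0;
* negative discriminant (speckle pushed the observable off the model
  manifold): the vertex −b/(2a) is taken, clipped to [0, s1];
* no root in [0, s1] (small negative c from noise): the nearest root is
  clipped in.

Admissibility uses a span-scaled tolerance (10⁻⁹·s1) so boundary cases
such as mv = 0 or mv = s1 are not spuriously flagged.

**Known limitation — bias at low polarized power.**  The spurious and
physical roots coincide as ms → 0, and under speckle the smaller-root rule
then biases mv low by roughly E[√(disc+noise) − √disc]/(2a).  At 81
effective looks this bias reaches ≈5% of s1 for strongly volume-dominated
targets (e.g. a mature rice canopy with very small surface return) and is
well below that elsewhere; the acceptance suite measures it for every
class and date of the default season.  More looks, or targets with a
non-negligible polarized component, shrink it rapidly.

## Optical conditioning

Scenes carry the 12 surface-reflectance bands of the L2A-style product
(B1–B9, B8A, B11, B12; the cirrus band has no surface-reflectance
counterpart) at native 10/20/60 m resolutions.  Resampling to the common
10 m grid is nearest-neighbour by default — it replicates coarse pixels
into blocks, which preserves piecewise-constant class means exactly and
is safe for categorical downstream use; bilinear is available by
configuration.  Cloud screening is a strict "less than" comparison of the
scene cloud fraction against the 0.20 threshold, so a fraction of exactly
0.20 is rejected, and raising the threshold can only accept more scenes
(monotonicity is tested).  All 12 bands enter the classifier by default;
the band list is configurable.

## Feature cubes and temporal experiments

A cube is a (rows × cols × bands) array with ordered per-band metadata
(sensor, date, feature); (sensor, date, feature) triples are unique, bands
are ordered by date ascending with a fixed within-date feature order, and
fusion concatenates optical bands before SAR bands.  Dates absent for one
sensor are simply absent bands — no temporal interpolation.  The
incremental experiments classify every chronological-prefix sub-cube; one
stratified split is drawn on the full sample set and re-used across
prefixes so that successive rows differ only by the bands available, not
by sampling noise.  The "best strategy" configuration fuses all 12 SAR
feature dates with the first six optical dates (January through late
August), dropping the two September scenes.

## Classification

Samples are pixels under labeled polygons (a pixel belongs to a polygon
iff its centre does; polygons of different classes must not overlap).
The stratified split tags round-half-up(0.7·n) pixels per class as train
(so 10 → 7/3 and 403 → 282/121), remainder test, both partitions forced
non-empty.  The split is pixel-level — matching the reference protocol —
which under spatial autocorrelation yields optimistic accuracy relative
to polygon-level validation; this caveat transfers to any real-data use.
The ensemble is a 150-tree random forest with library-default tree
hyperparameters and a fixed random state; per-(date, feature) impurity
importances are summed across dates per feature name and divided by the
maximum, so the top feature scores 1 by construction.

## Accuracy assessment and separability

Confusion matrices are oriented rows = predicted, columns = ground truth.
PA_j = 100·m[j,j]/colsum_j, UA_i = 100·m[i,i]/rowsum_i, OA =
100·trace/total, kappa = (p_o − p_e)/(1 − p_e).  Classes with an empty
row or column are reported as NaN (undefined), never as 0.  Percentages
and kappa are rounded to two decimals in reports.  The published 8-class
reference table used for validation contains three cells that disagree
with their own counts at the last digit (a soybean PA printed 95.85 vs
95.83 computed, a corn PA printed 85.11 vs 80.11, and an OA printed 94.20
vs 94.19); the implementation reports the count-derived values and the
tests assert those, with the OA compared within 0.05.

The Jeffries–Matusita distance uses the multivariate-Gaussian
Bhattacharyya distance D_B = ⅛ Δμᵀ M⁻¹ Δμ + ½ ln(det M / √(det Σ_p det
Σ_q)), M = (Σ_p+Σ_q)/2, with JM = 2(1 − e^(−D_B)) ∈ [0, 2].  Sample
covariances are regularized by adding 10⁻⁶ × mean-diagonal to the
diagonal; a still-singular pooled covariance raises an error naming the
pair.  Because the published separability table does not state which
feature set or dates it was computed on, JM is exercised on synthetic
data only.

## Synthetic scene generator

The generator defines the study conditions for all tests.

**Landscape.** Rectangular fields with per-class counts (default scaled
down from the reference survey's polygon shares: rice-dominated, corn
scarce) placed uniformly at random without overlap on a grassland
background; an integral-image search finds admissible positions exactly,
so placement fails only when no free slot exists.  Axis-aligned
rectangles are the simplest geometry producing contiguous training
polygons.

**SAR.** Each class carries a seasonal trajectory of (mv, ms, α_p, δ_p)
built from Gaussian phenology bumps over day-of-year: rice flooded early
(surface-dominated) and volume-peaking in late August; soybean and corn
peaking mid-summer with corn adding a late dihedral-like polarized term;
perennial ramie with a long flat season; stable water (low power),
forest (high volume), grassland, and building (strong polarized return,
α ≈ 75°).  Power units are linear and arbitrary but in the range of
typical C-band backscatter (0.005–0.8).  The true pixel Stokes vector is
mv·sv + ms·sp — exactly the model the decomposition inverts, giving exact
noiseless round trips.  Speckle follows the fully-developed model:
single-look channel vectors drawn as zero-mean circular complex Gaussians
with the class covariance, L-look averaging giving complex-Wishart
covariances whose expectation is the true covariance (verified by Monte
Carlo at 10⁴ looks, each element within 5% of the span).  Within-class
variability is a unit-mean lognormal power scaling with configurable
relative sd (default 0.10); it leaves class-mean covariances and, by
scale equivariance, class-mean decompositions unbiased.

**Optical.** Class means are linear mixtures of vegetation / soil /
water / built-up end-member spectra driven by a fractional-cover
phenology curve; additive Gaussian noise (default sd 0.02) is clipped to
[0, 1].  Clouds are unions of random disks grown until the requested
scene fraction is covered, overwriting reflectance with a bright
class-independent value (0.85 ± 0.03) and recorded in a mask; the default
season is clear except a 15% fraction on the last September date (below
the 20% screen, mirroring a late-season degraded scene).  Bands at 20/60 m
are produced by block-averaging the 10 m field so grid resampling is
exercised downstream.

**What passing tests do and do not show.**  The generator produces
piecewise-constant classes with stationary speckle/noise; it has no
incidence-angle variation, topography, mixed pixels, co-registration
error, atmospheric residuals or label noise.  Classification accuracies
on it (OA → 100% with the full fused cube) therefore validate the
plumbing, the decompositions and the qualitative temporal behaviour —
not real-world accuracy levels, which the published study obtains from
field data.

## Problem sizes and determinism

Default canned experiment: 96×96 pixels at 10 m, 12 SAR + 8 optical
dates, ~2 200 labeled pixels; the full study runs in ~20 s on one CPU.
The test suite uses 44–128 pixel grids; the speckle-recovery check pools
3 seeds × 1 296 interior pixels per class and date.  Every stochastic
stage takes an explicit seed; pipeline stages derive per-stage sub-seeds
by hashing (seed, stage, date), so runs are bit-reproducible end to end
and no global random state exists.
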