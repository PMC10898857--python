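# Methods

This note documents the models, numerical choices and known limitations of
the pipeline, in the order the data flow through it.

## Profile processing

A trial is a time-ordered sequence of digitized right half-profiles, one per
fashioning gesture, with gesture 0 the preform (the clay body right after
centering and opening). Processing steps and their parameters:

- **Calibration**: a single cm-per-pixel factor per recording; no lens
  correction (upstream of this package).
- **Resampling**: 256 points at regular intervals along the vertical axis,
  with x linearly interpolated. Where a profile overhangs (x multivalued in
  y, as in strongly necked forms), the vertical grid cannot represent it;
  such profiles are resampled at regular normalized arc length instead and
  flagged (`parameterization="arclength"`). Resampling is idempotent.
- **Smoothing**: a zero-phase (forward–backward) second-order Butterworth
  low-pass on the x series with default cutoff 0.1 of the point-index
  sampling rate, reflective padding at the ends. The source recordings do
  not fix a filter family or cutoff; zero-phase filtering was chosen because
  it adds no along-profile shape bias, and the cutoff is exposed in config.
  Smoothing is applied once, at ingest; the file-reading layer itself leaves
  profiles unsmoothed so that write/read round-trips are exact.
- **Mirroring**: the contour starts at the on-axis rim point, traverses the
  right edge downward and returns along the mirrored left edge (x ↦ −x);
  on-axis endpoint duplicates are merged, giving 2·256 − 2 distinct points.
  The fixed start point and traversal direction pin the Fourier phase, which
  is what makes the symmetry reduction below exact rather than approximate.

## Elliptical Fourier descriptors

The Kuhl–Giardina expansion of the closed contour is computed from the
closed-form per-segment sums for a piecewise-linear contour, by default in
the chord-length parameterization (cumulative edge length as the traversal
parameter). A `uniform` parameterization (equal parameter increment per
vertex) is also provided; the two differ for eccentric shapes — notably, an
ellipse is exactly single-harmonic only in its trigonometric (uniform-angle)
parameterization, a fact the test suite pins down.

For a bilaterally symmetric contour with the start-point convention above,
x(t) is odd and y(t) even in the traversal parameter, so the aₙ (cosine
terms of x) and dₙ (sine terms of y) vanish identically. The implementation
computes all 120 coefficients, asserts the suppressed half is numerically
null (the largest suppressed magnitude relative to the first-harmonic
magnitude is kept as a QC statistic, with a warning above 1e−3), and retains
the 30 pairs (bₙ, cₙ).

**Size normalization** divides all 60 retained values by the Euclidean norm
of the first pair, the simplest convention that is strictly scale-invariant;
an alternative (division by the first harmonic's semi-major axis) is
available behind a flag. No rotation normalization is applied: all outlines
share the vertical wheel axis by construction, so orientation is already
standardized.

Truncation at 30 harmonics reproduces the generator's outlines to an RMS
contour deviation of 0.02–0.2% of vessel height (measured as point-to-
polyline distance).

## Shape space and stages

The pooled PCA is a covariance (not correlation) PCA of all size-normalized
coefficient vectors: the coefficients share a scale after normalization, so
no per-coordinate standardization is warranted. Axis signs follow a
deterministic convention (largest-magnitude loading element positive) so
trajectories are bit-reproducible. Variances at numerical-noise level are
truncated to exactly zero so degenerate inputs report zero variance.

Stage snapshots are taken at gesture indices: preform = 0, final = last,
middle = round((n−1)/2) with the half-up rule. The gesture-count midpoint
was chosen over the elapsed-time midpoint because gesture timing is
irregular and occasionally long-tailed; a time-based midpoint is a
configuration option. A two-outline trial has a degenerate middle (flagged).

## Cross-projection subspace similarity

Each trial's coefficient sequence is centered by its own mean; V₁ is the
variance captured by its top-3 principal axes (population convention, divide
by n, so ratios are sample-size free). For the cross term V₂, trial A's data
are centered by **A's own mean** before projection onto B's axes: "variance
explained" is a property of A's scatter, and using B's mean would conflate
location with orientation differences. The choice is switchable. V₂ ≤ V₁
holds analytically (PCA optimality) and is asserted. Trials with fewer than
4 outlines cannot support a 3-D subspace and are excluded with a warning.
D = 1 − S is symmetric with zero diagonal but need not satisfy the triangle
inequality, and is treated purely as a dissimilarity.

## Distance-based tests

**Alternative Gower.** Mean absolute difference over columns that are not
zero in both observations. For continuous Fourier coefficients double zeros
essentially never occur, so the distance behaves as a city-block distance
scaled by the column count; the double-zero rule matters only for sparse
inputs.

**Nested PERMANOVA.** Sums of squares are partitioned from the squared
dissimilarity matrix via within-group sums (see the module docstring for the
identities). Degrees of freedom are design-derived: communities − 1 for the
community factor and potters − communities for the individual factor. The
permutation schemes match the exchangeable units under each null: whole
potters are permuted across communities (preserving the community potter
counts) for the community test, and observations are permuted among potters
within each community for the individual test. P-values use the
(b+1)/(m+1) estimator, which includes the observed statistic and never
returns zero. The library default is 10,000 permutations; tests and the
acceptance script use 199–999 at desk scale. A community with one potter
(or a one-community design) skips the community test only; a potter with a
single observation is a design error.

**Dispersion.** The dissimilarity matrix is embedded by principal
coordinates (double-centering of −½D²); squared distances to group
centroids are computed on the real axes minus the contribution of
negative-eigenvalue axes, clipped at zero with a logged diagnostic. The
homogeneity test is the one-way F on those distances with label
permutations. For Euclidean input the PCoA route reproduces direct
distances to the group mean exactly (asserted to 1e−8).

**UPGMA.** Average linkage via scipy's agglomeration; node heights are half
the cophenetic distance (two leaves at distance d merge at height d/2), and
the Newick export writes branch lengths so that every leaf sits at the root
height (ultrametric). Ties are resolved deterministically by input order.

## Hierarchical smooth-trajectory models

PC1–PC3 are modeled separately as functions of percent time on [0, 100]
with cubic B-splines (10 basis functions per smoother, clamped uniform
knots) and a second-order difference penalty formed from divided differences
at the Greville abscissae — this makes the penalty null space exactly the
straight lines in t, including near the clamped ends, so the strong-penalty
limit is an honest linear fit. Smoothers carry a sum-to-zero constraint
(absorbed by a null-space reparameterization) against the intercepts.

- **G**: intercept + one global smoother.
- **S**: community intercepts + one smoother per community sharing a single
  smoothing parameter. No additional global smoother is included (the
  group-specific-only variant); with few groups the two variants fit the
  same column space and the simpler one is identifiable without extra
  constraints.
- **SI**: model S plus potter intercepts (ridge-penalized) and potter
  deviation smoothers penalized by difference-plus-ridge, all sharing a
  second smoothing parameter. The ridge component shrinks the potter terms
  to zero in the strong-penalty limit, so SI nests S — the factor-smoother
  construction for "random-effect smoothers per potter".

Smoothing parameters minimize a restricted-likelihood (REML) criterion with
the scale profiled out, over a deterministic log₁₀ grid (step 1.5 over
[−3, 7], a 2-D grid for SI) followed by three local refinement passes, so
fits are bitwise reproducible. Model comparison uses conditional AIC,
−2ℓ + 2(edf + 1), with edf the trace of the influence matrix and +1 for the
scale. Out-of-sample deviance on the held-out even trials is the Gaussian
deviance 2(ℓ_saturated − ℓ_model) at unit dispersion, i.e. the sum of
squared prediction errors — deliberately *not* divided by each model's own
training scale, which would make deviances incomparable across models of
different flexibility.

## The synthetic generator

The generator's defaults are the study conditions: 3 communities (PR, MK,
FR) with 9/6/6 potters, 5 trials per potter, 8 vessel types (cylinder /
bowl / sphere / vase at 0.75 and 2.25 kg), 6–14 gestures per trial, 256-point
profiles.

Shapes live in a 4-D latent space — log aspect ratio (height/diameter),
linear taper, mid-height belly, rim flare — mapped to a 6-control-point
radius-vs-height template, interpolated shape-preservingly (PCHIP) and
pinched onto the axis at both ends so the mirrored contour closes. Absolute
sizes follow the two clay masses (height = size·a^{2/3} with size 14 cm for
0.75 kg and 20 cm for 2.25 kg), with aspect ratios per vessel type taken
from the study's descriptive means. Keeping shape variation in a low-
dimensional latent space is what concentrates the pooled PCA variance in a
few components, as observed in the real data.

A trial's path interpolates latent coordinates from the community's preform
template (tall barrel for PR, flat disk for FR, intermediate for MK) to the
vessel-type final template along a potter-specific monotone schedule
s_k = (k/(m−1))^γ, plus a sin(πs) waypoint term carrying the community's
style of change (PR overshoots in height before shortening; FR passes
through a wide-bottomed phase; MK is gradual) and potter/trial waypoint
variation. Hierarchical Gaussian effects on the latents use scales
σ_community = 0.10, σ_potter = 0.05, σ_trial = 0.02 (latent units, chosen so
community ≈ 2× potter ≈ 5× trial scatter — the "more variation among than
within" regime), plus σ_measurement = 0.02 cm of independent noise on
profile x-coordinates. A stage schedule multiplies potter- and trial-level
variability from 1.6 at the preform down to 0.6 at the final form; together
with the convergence of all community paths onto shared type templates this
reproduces the narrowing range of shape variation along morphogenesis.
Community waypoint magnitudes were set during design so that middle-stage
community separation stays below the preform separation, keeping that
narrowing monotone.

All randomness derives from a single seed through spawned per-potter and
per-trial substreams, so datasets are bitwise reproducible and any subset is
regenerable. Null variants remove community-level structure (shared mean
preform template and waypoint, zero community offsets), potter-level
structure, or both — the configurations used for type-I-error calibration.

**What the generator does not emulate**: real digitization noise structure
(tablet tracing errors are not i.i.d. Gaussian), open-rim geometry (the
pinch closes every silhouette at the rim, so aperture features are absent),
clay mechanics (no mass conservation along the path), and the absolute
dimension tables of the original study. Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline on data with
the study's hierarchical structure — not properties of the original
recordings.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at sizes chosen as desk-scale analyses:
permutation tests use 199–999 permutations (library default 10,000);
type-I-error calibration uses 1,000 null datasets of a reduced design
(3 communities × 3 potters × 3 trials, two gestures per trial); power,
dispersion-ordering and model-selection checks use the full 9/6/6 × 5-trial
design restricted to one vessel type per run (the analyses are per vessel
type), with 50, 50 and 20 replicate runs respectively. The acceptance
script generates the complete default study (840 trials, ~8,300 outlines)
and analyzes the vase (2.25 kg) condition plus the pooled preform test.

## Known limitations

- The y-grid resampling cannot represent horizontal rim/base faces or
  overhangs; the arc-length fallback preserves such shapes but changes the
  point spacing convention for those profiles.
- The 1 − S dissimilarity compares subspace orientations only; two trials
  with identical subspaces but opposite traversal directions are
  indistinguishable to it (the GAM layer is sensitive to direction).
- The nested PERMANOVA assumes potters are exchangeable across communities
  under the community null; systematic per-community differences in trial
  counts would weaken that exchangeability.
- REML optimization is grid-based; smoothing parameters are reproducible but
  resolved only to the refinement step (≈0.06 in log₁₀λ).
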