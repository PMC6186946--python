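# Methods

This note documents the models and procedures implemented in `epihs`, the
parameters that matter, the synthetic world the tests run in, and the
numerical and design choices made where the underlying study leaves the
design open. It states no empirical result that the test suite or the
analysis scripts do not themselves compute.

## 1. Surface model and template

Analyses live on a left–right **symmetric template**: both hemispheres have
the same vertex count and cross-hemisphere correspondence is identity of
index (the role fsaverage_sym plays for real cohorts). The synthetic
template is a mirrored pair of subdivided-icosahedron shells: the white
surface is a sphere (default radius 49 mm; subdivision level 4 gives
10·4⁴+2 = 2562 vertices per hemisphere), and the pial surface inflates it
outward along the radial normal by a smooth thickness field.

The thickness field spans **3–5 mm**. Two reasons: pediatric temporal
cortex is thick (3–4.5 mm), and at 1 mm isotropic voxels a thinner ribbon
leaves no room between the gray–white intensity transition and the
50 %-depth sampling footprint, which would bias the FLAIR normalization
anchors (a real effect, but one that would dominate the synthetic
validation rather than exercise it).

Coordinates are world mm, RAS; voxel indices 0-based.

## 2. Per-vertex features

- **Thickness** `T(v)`: symmetric mean of the two directed minimum
  point-to-mesh distances between corresponding pial and white vertices.
  The symmetric form resolves the directional ambiguity of a "mean minimum
  distance" definition and is self-consistent (both orderings agree).
  Point-to-mesh distances are exact point–triangle distances with KD-tree
  candidate pruning.
- **Gray–white contrast** `C(v) = |GM|/|WM|`: GM from T1 at depth fraction
  0.30 above the boundary, WM at 1 mm below the boundary along the inward
  white-surface normal (area-weighted vertex normals). The percent-contrast
  variant `100·(WM−GM)/(½(WM+GM))` is available (`gwc_variant="percent"`);
  the ratio is the default. `WM = 0` masks the vertex.
- **Normalized FLAIR** `RI(v) = (I(v) − GMpeak)/(GMpeak − B)` with `I`
  sampled at depth 0.50. `GMpeak` and `B` are histogram **modes**: 100
  equal-width bins over the [2nd, 98th] percentile range with parabolic
  refinement through the peak bin and its neighbours (validated against a
  dense-KDE argmax oracle). Both hemispheres are pooled ("across the
  brain"). `B` is sampled at depth fraction 0 — on the boundary — since the
  study names only "the gray–white matter boundary". `GMpeak = B` is an
  error, not a silent fallback. `RI` is exactly invariant to affine
  rescaling `I → aI + b (a > 0)` because percentile ranges, bin edges and
  parabolic refinement are all affine-equivariant; this invariance is the
  point of the normalization and is asserted to 1e-6 in the tests.

Sampling is trilinear; positions outside the grid are masked (NaN), never
clipped. Masked vertices always carry NaN, never a silent zero.

## 3. Mesh smoothing (10 mm FWHM)

Features are smoothed with an iterated **symmetric doubly-stochastic
diffusion** on the white-surface edge graph:
`S = I − (α/d_max)(D − W)` with inverse-edge-length weights `W`,
`D = diag(W·1)`. Per step the per-axis variance added is
`(α/d_max)·mean_i(Σ_j d_ij)/2`; the schedule chooses `n ≥ 20` iterations and
`α ≤ 1` so that `n · per_step_variance = FWHM²/(8 ln 2)` exactly (the
variance–FWHM identity; enforced within 1 %). Double stochasticity makes
every step preserve the mean over in-mask vertices exactly — the operator is
rebuilt on the masked subgraph, so masked vertices neither receive nor
donate mass; on a denser subgraph the schedule adds iterations rather than
exceed the stability bound. On a flat triangular lattice the impulse
response matches the closed-form 2-D Gaussian within 4 % out to 8 mm
(asserted at 10 %). FWHM below half the mean edge length degenerates to the
identity with a warning.

## 4. Harmonization

Features are z-scored per vertex against the healthy controls
(`σ` with denominator n−1) **before** hemispheres are flipped into the
ipsi/contra-lesional frame — the enforced order, recorded per subject in a
flip log. Vertices with zero control variance are masked with a warning
count. Right-lesion patients have their hemisphere blocks swapped (exact,
because correspondence is index identity). Controls are left unflipped by
default (`control_policy="as-is"`, the minimal assumption; a seeded
`"random-half"` option exists and the choice is always logged, never
silent).

## 5. Vertex-wise statistics

Ordinary least squares per vertex, design = intercept + group indicator +
age (hippocampal models add ICV); `t(v) = c'β̂/(σ̂(v)·√(c'(X'X)⁻¹c))`,
`df = n − rank(X)`. Zero-variance vertices are masked from inference rather
than clipped to ±∞. Residuals are retained.

**Smoothness / resels.** Residuals are normalized to unit norm across
subjects per vertex; for each edge, `λ̂_e = Σ_subj (u_i − u_j)² / d_e²`
estimates the derivative variance of the unit-variance error field
(`FWHM_e = √(4 ln 2 / λ̂_e)`). Triangle resels are
`area · mean(λ̂ over its 3 edges) / (4 ln 2)`; vertex resel densities take
one third per incident triangle. The estimator recovers an applied 10 mm
smoothness within ~±10 % and is exactly invariant to uniform rescaling of
the mesh.

**RFT cluster correction.** Clusters are edge-connected excursion sets
above the one-sided cluster-defining threshold `t_c = t⁻¹(1 − cdt_p, df)`
(default `cdt_p = 0.025`), in both directions. With
`R₂` total resels and EC densities of a t field

    ρ₀(t) = P(T ≥ t),
    ρ₂(t) = (4 ln 2)/(2π)^{3/2} · Γ((ν+1)/2)/(√(ν/2)·Γ(ν/2)) ·
            t·(1+t²/ν)^{−(ν−1)/2},

the expected cluster count is `E[m] = R₂·ρ₂(t_c) + R₀·ρ₀(t_c)` (the
boundary-free closed surfaces contribute no R₁ term), the expected
supra-threshold area in resels is `E[A] = R₂·ρ₀(t_c)`, cluster extent `k`
(in resels, i.e. nonisotropy-corrected) has the 2-D exponential tail
`P(S ≥ k) = exp(−(E[m]/E[A])·k)`, and
`p_FWE = 1 − exp(−E[m]·P(S ≥ k))`. Because both directions are tested,
`E[m]` and `E[A]` are doubled, so α = 0.05 is controlled over the
two-direction family — consistent with reading "cluster-defining threshold
0.025" as the two-sided 0.05 split per direction. Monte-Carlo calibration
on null cohorts puts the empirical family-wise error at ≈0.047 (600 runs
during development; the acceptance test asserts the [0.02, 0.075] band on
200 runs).

**Permutation oracle.** Freedman–Lane: nuisance columns are regressed out,
their residuals permuted, the full model refit, and the maximum cluster
resel extent over both directions forms the null distribution;
`p = (1 + #{perm ≥ obs})/(1 + n_perm)`. RFT and permutation p agree within
a factor of 3 for clusters with RFT p in [0.01, 0.2] and always agree in
rank order (same extent statistic).

**Cluster Cohen's d** is computed on subject-level cluster means with the
pooled n₁+n₂−2 denominator. Note an intrinsic property: because the noise
is spatially correlated, a cluster mean has noise SD < 1 (in z units), so
cluster d systematically exceeds the planted per-vertex d. The test suite
therefore validates d against its closed-form expectation under the
generator (planted d × mean patch profile ÷ cluster-mean noise SD computed
from the noise covariance) rather than against the per-vertex d.

## 6. Hippocampal quantification

Volume = voxel count × |det(affine linear part)|; empty masks are errors;
volume is invariant to rigid reorientation. Mean RI over the mask uses the
same normalization context as the subject's cortex (the shared-equation
reading; flagged in config). Group models are
`measure ~ group + age + ICV` per side, with patients compared to
side-matched control hippocampi so anatomical left/right asymmetry stays
out of the group term. Within patients, classical paired t on
(ipsi − contra); constant nonzero differences are flagged degenerate
(|t| → ∞) rather than reported as finite.

## 7. Clinical models

Cluster-level OLS `feature ~ FC + onset + duration` reports **both**
two-sided and one-sided p per term (display default two-sided; the choice is
never silent — the published FC result is consistent with a one-sided
test). Pearson correlations use the classical t-based p. The
radiological-blurring subgroup contrast is a pooled-variance two-sample t
by default (Welch available). Missing IQ values are excluded pairwise and
never imputed. Demographics aggregation is missing-aware; with a single
record the SD is reported as missing.

## 8. The synthetic world — and what a green test does not establish

The generator emulates the cohort's statistical structure, not brain
geometry:

- **Geometry**: spherical shells instead of folded cortex. The claims under
  test are statistical (calibration, recovery, invariances); folding would
  add realism but no coverage. Consequently nothing here validates surface
  reconstruction, registration, or the effect of cortical curvature on
  smoothing anisotropy beyond what mesh-edge nonuniformity induces.
- **Demographics** follow the published marginals with fixed counts
  (22 patients 13:9 left:right, 9/22 febrile convulsions, 10/22 blurring,
  age 10.53 ± 3.32 vs 14.33 ± 3.01; onset + duration = age).
- **Planted cortical effects**: a geodesic patch (default radius 25 mm,
  ≈2000 mm² ≈ 6.5 % of a shell hemisphere — the scale of the extensive
  mesial-plus-lateral anterior temporal involvement the study describes)
  with a 6 mm tapered profile, at the published cluster effect sizes:
  FLAIR d = +1.48, contrast blurring d = +2.06, thinning d = −0.95, in
  between-subject SD units (SDs: thickness 0.25 mm, contrast 0.05,
  RI 0.30 — typical single-site values). Modulators add to patient shifts:
  febrile convulsions +0.4 SD on patch FLAIR; radiological blurring
  +0.6 SD on contrast and +1.2 SD on FLAIR (magnitudes chosen once to be
  consistent with the published t statistics; the study prints no effect
  magnitudes for these).
- **Noise**: per-subject spatially correlated fields made by diffusing
  white noise on the mesh to 15 mm FWHM and normalizing to exactly unit
  per-vertex variance (the study states no within-cohort spatial
  covariance; 15 mm is a generator choice, flagged in config, and is what
  makes the RFT smoothness machinery do real work). Age slopes
  (−0.02 mm/yr thickness, −0.002/yr contrast, −0.005/yr RI) exercise the
  age covariate against the groups' age gap.
- **Hippocampi**: ellipsoidal labels whose voxel counts realise the planted
  volumes exactly (patients 2780 ± 341 mm³ ipsi / 3210 ± 388 contra;
  controls ≈3300 ± 300 per side), coupled to ICV (150 mm³ per ICV SD;
  ICV ~ N(1.4·10⁶, 1.2·10⁵) mm³ — sampled, not derived from the bounding
  volume, which would be nearly constant across identical shells); RI
  shifts +0.25 ipsi / +0.15 contra over SD 0.20.
- **Volumes** (full fidelity): WM/GM/CSF plateaus with a linear T1 depth
  profile, a 1.2 mm FLAIR transition just above the boundary (keeps the
  boundary mode at the WM value), a trapezoidal mid-depth FLAIR bump for
  planted hyperintensity, GM–WM mixing for planted blurring, and iid
  Gaussian voxel noise (SD 2). No bias fields, motion, or scanner
  artifacts — partial-volume behaviour at 1 mm voxels is the only
  acquisition realism.

`GroundTruth` records the planted regions (defined as the support of the
expected group difference at ≥ 0.5 between-subject SD — the set recovery
Dice is scored against), profiles, slopes and hippocampal means; the
pipeline never reads it.

## 9. Degenerate inputs and tie-breaks

- Histogram mode of identical samples returns that value; peak at a
  histogram edge skips parabolic refinement; refinement offsets are clipped
  to half a bin.
- Hippocampal mask voxel selection orders by the ellipsoid quadratic form
  with a stable sort, so planted volumes voxelise deterministically.
- `cdt_p = 1` thresholds at −∞ and returns one cluster per mesh component.
- Subject failures in feature extraction mark the subject failed in the
  manifest and shrink the cohort; stages log the reduced n. Stages starved
  below their minimum n (e.g. < 5 patients for the clinical model) log a
  failure and are marked absent in the report instead of aborting the run.
- Determinism: a cohort is fully determined by its seed; the pipeline's
  manifest hashes are identical across reruns (HDF5 written without
  timestamps, MGH/CSV/JSON inherently stable).

## 10. Known limitations

- RFT cluster p at a cluster-defining threshold as low as p = 0.025 relies
  on the exponential extent approximation; it is accurate here (calibration
  ≈ nominal) but the permutation test remains the reference for borderline
  clusters.
- The spherical-shell world cannot probe errors specific to folded
  geometry: gyral/sulcal anisotropy, registration error, or
  partial-volume structure beyond a radial ribbon.
- Cluster Cohen's d is a biased estimate of per-vertex effect size by
  construction (see §5); published cluster d values and simulated ones are
  comparable only through the generator's covariance model.
- The real study's t values, cluster topographies and figure-level results
  are not reproducible without its MRI data; this package establishes that
  the *method* detects the published effect structure at the published
  effect and sample sizes, not that it reproduces the original maps.
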