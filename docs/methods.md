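# Methods

## Measurement model

All geometry uses image pixel coordinates with 0-based integer pixel
centers, origin top-left, y increasing downward. The *temporal* reference is
the horizontal ray from the optic-disc center toward the fovea's side, so no
assumption about left/right image orientation is ever needed; only right
eyes are handled (no mirroring).

* **Vessel angles** are unsigned angles in [0°, 180°) between the
  disc-center→crossing ray and the temporal horizontal; ST/IT angles are
  reported as magnitudes. The crossing points are annotations on the
  208-pixel measurement circle (validated to ±1 px), not image detections.
* **PMP** is signed, positive when the fovea is inferior to the disc-center
  horizontal; its magnitude cannot exceed 90° by construction.
* **Ovality ratio** is the minimum over directions of the disc boundary's
  directional width divided by the maximum, evaluated on 3,600 uniformly
  spaced directions in [0, π). This brute-force sweep is the reference
  algorithm; its worst-case angular discretization error is far below the
  0.01 tolerance used in the round-trip tests. Fewer than 8 boundary points
  or a collinear boundary is a geometry error.
* **Sampling circles.** The sizes "208", "96" and "32 pixels" are
  interpreted as circle *diameters* (configurable, since radius vs diameter
  is ambiguous in common usage). A pixel belongs to a circle when its center
  lies inside the disk. The eight peripapillary circles sit on a ring
  concentric with the disc with radius = (max disc semi-diameter) +
  (sampling-circle radius), i.e. tangent to the disc margin; L1 lies on the
  disc→fovea line and subsequent loci advance in 45° steps counterclockwise
  on the displayed image. The exact ring-placement rule of the original
  ImageJ workflow is not published; the tangent rule is this package's
  choice and is exposed as a parameter.
* **TFI** = R/(R+G+B) of the circle's mean intensities; an all-black circle
  makes it undefined, which is recorded as a missing value, and subjects
  with any missing parameter are excluded listwise from model fitting.

A note on symmetry: with a *horizontal* temporal reference, vessel-angle
magnitudes are preserved under 180° rotations of the scene (the reference
follows the fovea's side) but are not well-defined under a 90° rotation,
which puts the fovea vertically above the disc. The tests therefore check
angle invariance under half turns and ovality invariance under quarter
turns.

## Sex model

Female is coded 1 so that an index near 1 means "feminine fundus"; the
conventional decision threshold is 0.5. Predictors are z-scored before
penalization and the intercept is unpenalized — standard ridge practice;
the penalized log-likelihood is maximized by damped Newton (IRLS with step
halving), tolerance 1e-8 on the gradient norm, at most 200 iterations. The
objective is strictly concave in the slopes for λ > 0, and near the optimum
steps are accepted within float rounding tolerance so the quadratic
convergence is not stalled by cancellation noise.

λ is selected once by 10-fold class-stratified cross-validation of the
held-out log-likelihood on the full data (grid 10⁻², …, 10², ties to the
larger λ) and reused across all LOOCV folds, matching a single-model
workflow; the mild optimism this induces in the LOOCV AROC is accepted and
documented rather than nested. Within each LOOCV fold the standardization
constants are recomputed from the 1,652 training eyes, and the held-out
prediction uses the fold's model only, so the held-out label cannot leak.

Two known artifacts of this design are worth naming. First, with an
unpenalized intercept, LOOCV predictions carry a small anti-correlation with
the held-out label through the fold prevalence (leaving out a woman lowers
the fold's female fraction); under the null (no sex effects anywhere) this
biases the LOOCV AROC slightly *below* 0.5 — roughly 0.46 rather than 0.50
at n = 400 with heavy shrinkage. The null-calibration test therefore checks
the mean AROC over seeds against a 3-SE band around 0.5, and the bias
vanishes as signal enters. Second, the λ grid is capped at 10²: letting λ
grow unboundedly makes the slope noise vanish while the prevalence artifact
survives, which would turn the null AROC degenerate.

AROC is computed from midranks (exactly the Mann–Whitney U over n₁n₀, ties
counted half), never from a trapezoid over an ROC polyline.

## Synthetic cohort

The generator's defaults are the study conditions of a ≥40-year-old island
population screening cohort: n = 1,653 right eyes with 838 men and 815
women; per-sex Gaussians (truncated at ±4 SD) for age (52.8 ± 9.4 /
54.0 ± 10.8 y), height (163.7 ± 6.3 / 151.1 ± 5.8 cm) and axial length
(23.71 ± 0.83 / 23.28 ± 0.88 mm); default seed 20050501, recorded in every
run manifest.

Scene parameters (4 vessel angles, PMP, ovality, 9 × RGB color loci = 33
values) are drawn on a standardized scale as

    z_j = (d_j/2)·s + l_j·u + noise_sd·sqrt(1 − l_j²)·ε_j ,

with s = ±1 for men/women, d the configurable standardized male−female
effect vector, u ~ N(0,1) a per-subject latent factor, and ε independent
noise; each z_j has unit variance by construction. Axial length is drawn as
μ_sex + σ_sex(ρu + sqrt(1−ρ²)e) so that corr(u, AL) = ρ within sex exactly
(`index_axial_rho`, default −0.13). The latent loadings default to the
feminizing direction −d/‖d‖ scaled by `latent_strength` = 0.6; because the
fitted index is only an estimate of the discriminant direction, the
*realized* within-sex index–axial correlation is an attenuated version of
ρ (about −0.08 to −0.12 at full cohort size), which is the expected behavior
of a plug-in index, not a calibration error. Body height is generated
independent of the fundus within sex, so any pooled index–height correlation
arises purely from the between-sex differences.

Per-feature effect sizes are not published for any cohort, so the default is
a fixed direction pattern that follows the reported adult sex differences —
rounder discs, steeper temporal vessels and stronger peripapillary reddening
(tessellation) in men; higher green/blue intensities in women — scaled once
so that the oracle (Bayes) linear-discriminant AUC,
Φ(√(dᵀΣ⁻¹d)/√2) with Σ = diag(noise) + llᵀ, equals 0.815. That target is
the separability implied by an index summary of 0.35 ± 0.23 vs 0.64 ± 0.23
and a reported ~80% classification accuracy in comparable adult data.

Ovality maps to (0, 1] through 1 − exp(−(2.0 + 0.3 z)) (baseline 0.865,
SD ≈ 0.04), which keeps the minor/major invariant without truncation and
gives a closed-form group mean (a lognormal moment) that the generator tests
check against Monte-Carlo. Angles and colors are affine in z with baselines
(66/64/70/68 ± 6–7° vessels, 6 ± 3° PMP, peripapillary ≈ (175, 88, 62) ± 12
and foveal ≈ (150, 66, 46) ± 12 intensity units) chosen so clipping to the
valid ranges is vanishingly rare.

### Rendering

Images are 768 × 768 8-bit RGB (resolution is a package choice; native
camera resolution is not published). The disc is a filled ellipse with a
fixed 80-px vertical semi-major axis and minor axis = 80 × ovality; the
fovea sits 300 px from the disc center along the PMP direction; four
straight vessel rays leave the disc at exactly the configured angles, so the
emitted crossing landmarks on the 104-px-radius measurement circle encode
the truth angles exactly. The eight peripapillary sampling disks and the
foveal disk are painted *flat* (with a 1.5-px margin) after the vasculature,
so circle-sampled means equal the color truth up to 8-bit quantization; the
geometry that matters to the index lives in the landmark files, not in
image content, and the images make no claim to photorealism. Disc-boundary
landmarks are 64 points on the ellipse — enough that the polygonal
approximation changes the ovality ratio by < 0.002. With these sizes the
ring of sampling disks is tangent to the disc and adjacent disks do not
overlap, so every sampled pixel carries its own locus color.

What the generator does **not** emulate: media opacity and illumination
gradients, vessel curvature and branching, disc pallor/cupping, real
annotation error in landmarks (landmarks are exact), and any age structure
in the fundus parameters. Passing tests therefore demonstrate correctness
of the *measurement and modelling machinery* under known truth, not
performance on real photographs.

## Association stage

Pearson and Spearman correlations are both reported for every pair/subgroup
(sources in this literature disagree about which was used, so the report
schema carries both); Spearman is computed as Pearson on midranks with the
t-approximation p-value. Sex comparisons use the Mann–Whitney U with the
tie-corrected normal approximation, two-sided, without continuity
correction (the large-sample convention of the classic clinical statistics
packages); when every pair is tied the variance vanishes and p = 1 is
reported. Significance is flagged at p < 0.001 throughout, the conventional
threshold for cohorts of this size. Stepwise regression is bidirectional
with entry p < 0.05 and removal p ≥ 0.10 (the named packages' defaults),
implemented on plain least squares with t-tests and verified against
statsmodels; selection stops if the current model becomes numerically exact.
Standardized coefficients are b·SD(x)/SD(y). Subgroups too small for a
statistic (n < 3 for correlations, fewer observations than candidates for
stepwise) are marked not-computable rather than raising.

## Problem sizes and determinism

The test suite runs the full n = 1,653 LOOCV (≈ 6 s), 100 render/extract
round trips, 200-cohort correlation-recovery sweeps and a 500-replicate
stepwise null calibration; the acceptance script repeats the full-scale
analysis end-to-end in under a minute. All randomness flows from a single
integer seed through `numpy.random.default_rng` seed sequences (one stream
for covariates, one per subject for scenes), so cohorts, landmark files and
feature tables are byte-identical across reruns with the same seed.

## Known limitations

* λ selection on the full data before LOOCV slightly flatters the LOOCV
  AROC; nested selection would cost ~10× runtime.
* The stepwise entry/removal thresholds and the ring-placement rule are
  conventions, not published facts; both are configurable.
* The oracle-AUC calibration is exact on the 33 scene parameters; the fitted
  model sees the 42 derived parameters (TFI adds near-collinear nonlinear
  combinations), so realized LOOCV AROC sits near, typically just above,
  the configured oracle at large n with CV-selected λ.
* The index–axial attenuation described above means the *configured* ρ is a
  latent-level quantity; consumers who want a target on the observed index
  scale must inflate ρ accordingly.
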