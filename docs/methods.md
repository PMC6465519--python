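# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `st1t2` package: what the synthetic cohort
emulates, how the standardized ratio is computed, and exactly which
statistics the cohort battery runs.

## The standardized ratio

For one subject with co-registered, bias-corrected T1w and T2w volumes and
a tissue mask set (brain, GM, WM, CSF, lesion), the package computes

* the classic ratio `T1w/T2w` voxelwise inside the brain;
* the scaling factor `s = median(T1w | NAGM) / median(T2w | NAGM)`, where
  NAGM = GM minus lesion voxels — the lesion-free anchor prevents
  gray-matter lesions from dragging the standardization;
* the standardized map `sT1w/T2w = (T1w − s·T2w) / (T1w + s·T2w)`.

On voxels where both inputs are strictly positive the standardized value
lies in (−1, 1), gray matter maps near 0 (by construction of `s`), white
matter is positive and CSF negative. If both modalities are multiplied by
arbitrary global gains `a` and `b`, the recomputed scaling factor becomes
`(a/b)·s`, so the standardized map is *exactly* invariant while the
classic ratio scales by `a/b`. This cancellation is the entire mechanism
by which standardization removes between-subject scanner-gain variability,
and it is asserted to 1e−10 relative tolerance in the tests.

Denominator guard: voxels whose denominator is below
`1e−6 × median brain intensity of the denominator image` are excluded from
the valid mask rather than producing huge or infinite values. Masked
medians use numpy's midpoint convention for even counts, stated here for
bit-reproducibility.

## Synthetic cohort

The generator produces, per subject, an integer label volume (background /
CSF / GM / WM / lesion), T1w and T2w volumes, and a subject table row. Its
defaults are the emulated study's conditions and are not tuning knobs.

**Subject table.** 47 MS / 47 HC; each MS subject has an HC partner of the
same sex with age within ±0.5 years (the matching tolerance "6 months"
interpreted exactly). Patient ages are truncated-normal 37.69 (9.22) years
on [21.5, 60.2]; 30 of 47 are women. Lesion counts are negative-binomial
by moment matching — MS 59.23 (46.75), HC 3.09 (3.58); both are
overdispersed, and a Poisson fallback covers variance ≤ mean. Lesion
volumes are lognormal by moment matching — MS 5.07 (6.86) ml, HC
0.07 (0.09) ml — sampled only when the count is positive, so volume is
zero exactly when the count is zero. EDSS lives on the 0.5 grid in [0, 6]
(discretized truncated normal around 2) and disease duration is lognormal
with moments 24.6 (57.57) months; both are absent for controls. The
head-size covariate is an analog of a brain-normalization V-scaling
factor: normal with mean 1.25, SD 0.06, women +0.08 above men on average
(inverse to physical head size). An optional switch blanks one subject's
head-size value to exercise listwise deletion along the stepwise path.

**Phantom geometry.** An ellipsoidal brain (semi-axes 0.84/0.74/0.70 of
the half field of view) with a nested CSF core (normalized radius ≤ 0.35),
WM interior (0.35–0.75) and GM shell (0.75–1). The head-size covariate
scales all radii by `(mean/h)^(1/3)`. Lesions are compact blobs grown as
nearest-available-WM-voxel sets around randomly sampled centers, with
per-lesion voxel budgets drawn from a lognormal and adjusted so the voxel
total matches the recorded lesion volume exactly (floored at one voxel per
lesion, since sub-voxel lesions are not representable); a lesion load
exceeding the WM volume is an error, not a silent truncation.

**Intensity model.** Tissue means (arbitrary units) default to
T1w 100/300/430/250 and T2w 120/60/40/90 for CSF/GM/WM/lesion — lesions
T1w-hypointense and T2w-hyperintense. The target NAWM standardized median

    s* = 0.41 − 0.02·[group = MS] − 0.001·(age − mean age) − 0.0004·count

is implanted by setting the WM T1w mean to `w(1 + s*)/(1 − s*)`, where `w`
is the WM value of the noiselessly scaled T2w. The implant goes through
the T1w side so the T2w gray-matter anchor stays group-neutral, matching
the observation that raw NAGM values do not separate the groups. Age is
centered at the *configured* mean age (not the realized sample mean) so
any subject can be regenerated without the rest of the cohort. Each
modality is then multiplied by a per-subject lognormal gain (log-SD 0.14
per modality — chosen so the classic ratio's between-subject CoV lands in
the high-teens-to-low-twenties percent range reported for real cohorts)
and by a smooth random bias field (exponentiated degree-2 polynomial,
maximum fractional deviation 0.2, unit mean over the brain), and Gaussian
noise with SD 2 intensity units is added before clipping strictly
positive. Noise is additive Gaussian rather than Rician: at the emulated
SNR the difference is negligible for medians, and Gaussian keeps them
unbiased.

**Determinism.** Every draw descends from the single configured seed plus
a stage code and a CRC of the subject id; identical configurations produce
byte-identical artifacts, and tests assert it.

**Grid.** The default grid is 64³ at 2 mm isotropic — deliberately coarser
and smaller than a clinical 1 mm whole-head acquisition so that a full
cohort simulates in seconds while every downstream contract is preserved.
The heavy cohort-level tests run 32³ at 4 mm, which keeps the same 128 mm
physical field of view (halving the grid without doubling the voxel size
would shrink the brain and make realistic lesion loads infeasible). All
problem sizes are configuration, not hard-coded.

**What the generator does not emulate.** No gyral anatomy, partial-volume
mixing, Rician noise floor, multi-site field-strength differences, FLAIR
contrast, or spatially structured (tract-specific) NAWM damage. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* under the stated generative assumptions, not the biological
validity of the ratio on real scans.

## Bias-field correction

Real pipelines use histogram-based nonparametric correction; this package
ships a self-contained log-domain polynomial corrector whose contract is
testable. Log intensity inside the brain is regressed on a 3D monomial
basis of total degree ≤ 2 (degree 1–3 selectable). Fitting a multi-tissue
image with a plain polynomial would absorb the radially arranged tissue
contrast into the "field", so when a tissue partition is available
(CSF/NAGM/NAWM/lesion — the pipeline always passes it) each tissue
contributes an intercept column and the polynomial part captures only the
smooth field. The returned field is the exponentiated polynomial,
normalized to unit mean over the brain, which also makes the estimate
invariant to global rescaling of the input. Non-positive voxels inside the
brain are excluded from the fit and logged, never clamped. Fewer fit
voxels than basis terms is a hard error. Each modality gets its own field.
Against a known degree-2 field on a clean phantom the estimate is accurate
to well under 2% RMS; the corrector is not, and does not claim to be, an
N3/N4 replica.

## Cohort statistics

* **CoV**: 100 × sample SD (n−1) / mean, across subjects on per-subject
  NAWM medians.
* **Equality of CoVs**: the asymptotic chi-square statistic
  `D = Σ mᵢ(cᵢ − c̄)² / (c̄²(0.5 + c̄²))` with `mᵢ = nᵢ − 1` and
  `c̄ = Σ mᵢcᵢ / Σ mᵢ`, referred to χ²(k−1). Its type-I error at α = 0.05
  is verified by Monte-Carlo (2000 null replicates at n = 47 + 47) to lie
  in [0.035, 0.065]. The two measures being compared come from the same
  subjects; treating them as independent samples replicates the emulated
  analysis and is a fidelity-over-optimality choice — the dependence makes
  the test conservative in the direction that does not matter here, given
  effect sizes of 3–10× in CoV.
* **Group tests**: Welch t with Welch–Satterthwaite df, two-sided, for
  every measure × region (NAGM, NAWM); significance gate p < 0.004
  (Bonferroni). Sex uses Pearson chi-square without continuity correction
  (on a perfectly balanced table the statistic is exactly 0 either way;
  uncorrected is the simpler contract). The age comparison is reported
  with explicit group order (HC − MS), since the emulated report's
  negative t is order-dependent.
* **Correlation**: Pearson r between classic and standardized NAWM
  medians, plus the adjusted R² of the simple linear fit.
* **Stepwise models**: OLS with sex entering only as Female:head and
  Male:head interaction columns — a bound pair that is removed as one
  unit, its p-value being the larger of the two. Backward path: remove the
  non-significant term with the largest p-value (threshold 0.05,
  deliberately pre-Bonferroni: the final-model terms of the emulated
  analysis sit at p ≈ 0.001–0.012, so a 0.004 removal gate would not
  reproduce them), refit with listwise deletion over the remaining
  columns (observation counts may grow along the path), stop when all
  remaining terms are significant. Every model's AIC is recorded on the R
  convention (−2 llf + 2(k+1), counting the residual variance) and the
  minimum-AIC model is selected. Note the two rules differ by design: the
  AIC pick is more liberal (its implicit keep-threshold for one term is
  near p = 0.157), so on null data the path endpoint is intercept-only in
  ~95% of replicates while the AIC pick keeps a spurious term more often.
  The age × duration interaction is a standalone term with no hierarchy
  constraint, matching the emulated model's behavior of dropping duration
  while keeping age.
* **Diagnostics**: maximum Cook's distance is recorded for every fitted
  model; values above 1 are flagged in the log and make the pipeline exit
  non-zero. Small cohorts (a dozen patients under an 8-column model)
  legitimately trigger these flags.

Whole-cohort models use group, age and the sex × head-size pair; the
patient-only models add EDSS, disease duration, lesion volume, lesion
count and age × duration. Because lesion count is strongly confounded with
group and is absent from the whole-cohort model, that model's group
coefficient estimates the *marginal* MS effect
(≈ effect_ms + effect_count × group difference in mean counts ≈ −0.043
under the defaults), not the structural −0.02; the structural coefficients
are identifiable, and recovered within 25%, when lesion count is included
as a predictor (the parameter-recovery test, n = 200 + 200).

## Known limitations

* The corrector assumes the true log-field is low-order polynomial; the
  generator honors that assumption, real N3/N4-style fields need not.
* The CoV-equality test ignores the within-subject pairing of the two
  measures (see above).
* CSF medians are computed on bias-corrected volumes; whether a real
  pipeline would use raw ones is a convention, fixed here one way.
* With all stochastic corruption disabled the implanted group effect is
  visible in raw T1w and classic-ratio medians too (it lives in the WM T1w
  mean); the selective sensitivity of the standardized ratio — group
  difference detectable in sT1w/T2w only — emerges under the default
  scanner-gain variability, which swamps the raw-intensity shift.
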