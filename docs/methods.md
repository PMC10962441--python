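# Methods

## Scope

`pvsalps` implements the quantitative core of a perivascular-space (PVS)
function analysis in cerebral small vessel disease: the DTI-ALPS index,
PVS volumetry from tissue-class maps, and the longitudinal statistics
relating both markers to CSVD burden, cognition and incident dementia.
Upstream steps that are manual or tool-bound in practice — tissue
segmentation, registration estimation, WMH delineation, lacune and
microbleed identification, eddy/motion correction, TBSS skeletonization
— are treated as inputs: label volumes, a 4×4 affine (identity for
template-space phantoms) and a skeleton mask.

## Diffusion signal model and tensor fit

The phantom generators and the fit share one physical model: the
monoexponential tensor model S = S0·exp(−b·gᵀDg) with D a symmetric
positive-definite 3×3 tensor in mm²/s. The fit is log-linear least
squares over (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), the default
behaviour of the standard command-line tensor tools. Choices:

* **Signal floor.** Log-domain fitting cannot accept S ≤ 0; such
  measurements are raised to `signal_floor_rel × S0` (default 1e-6) and
  counted per voxel, so degenerate measurements are visible in QC
  instead of producing −inf or being silently dropped.
* **Polarity.** The emulated acquisition measures 25 directions at
  b = 1000 s/mm² in positive and negative polarity plus 8 b = 0 volumes
  (2.5 mm isotropic). Polarity pairs enter the fit as independent
  measurements, not averages; whether the reference workflow averaged
  them is unstated, so this is an explicit switchable choice
  (`polarity` in the phantom spec controls emission).
* **No eigenvalue clamping.** Voxels with λ3 < 0 (noise) are flagged
  and counted in ROI QC; clamping would hide noise problems.
* **Axis convention.** Dxx/Dyy/Dzz are tensor diagonal entries in a
  right–anterior–superior frame (x = left–right, y =
  anterior–posterior, z = inferior–superior); phantoms are generated in
  that frame, file-based inputs are assumed reoriented upstream.

On noiseless phantoms the fit is exact to numerical precision; the test
suite asserts agreement with planted tensors to 1e-10 mm²/s and FA
against the closed-form eigenvalue formula.

## ALPS index

ROI geometry follows the standard template-space definition: four
6-mm-diameter spheres at (24, −12, 24), (−28, −12, 24), (36, −12, 24),
(−40, −12, 24) mm. The published coordinate list carries no role
labels; roles are assigned by anatomy — the medial sphere per side
(smaller |x|) is the projection ROI (corona radiata lies medial to the
superior longitudinal fasciculus). This assignment is a config default
and overridable.

ROI means are taken in template space: a 1-mm sampling lattice inside
each sphere, diffusivity values pulled from the maps by trilinear
interpolation through the composed (map affine × map-to-template)
transform, validity by nearest neighbour. This matches the direction of
the reference workflow (individual maps registered to the template).
Rasterization onto an arbitrary grid is voxel-center-in-sphere with no
partial volumes — deterministic and checkable against brute-force
enumeration (a radius-3 sphere on a 1-mm lattice centred on a node
contains 123 voxels).

Orientation QC replaces the visual fiber-direction check: per ROI, the
fraction of voxels whose principal eigenvector is dominant along the
expected axis (z for projection, y for association), with a warning
below a configurable threshold (default 0.5). QC is advisory; ROIs are
never moved.

Failed-fit voxels are excluded from ROI means and counted, so a single
bad voxel cannot silently bias a sphere mean. A non-positive
denominator (Dyy_proj + Dzz_assoc ≤ 0) is an error, not a number.

The closed-form phantom plants uniform axis-aligned tensors in
4.9-mm-radius regions around each ROI centre on a 1-mm grid whose
affine is an integer-mm translation, so sampling points coincide with
voxel centres and the computed index equals the planted arithmetic
exactly; the planted filler diffusivity on the dominant axis is set
above every planted value so eigenvector orientations are as intended.
Note the standard ROI centres are *not* left–right mirror images
(|x| = 24/36 vs 28/40), so mirror-symmetry of the index holds only for
a mirror-symmetric ROI override, which is how the property is tested.

## PVS volumetry

PVS map = CSF ∖ (lacunes ∪ ventricles ∪ vessel/extra-cerebral CSF),
with union semantics (overlapping exclusions subtract once). The
"CSF surrounding large vessels and outside the brain" has no published
algorithm (it was a manual step); it is an explicit exclusion mask in
`TissueMaps`, which the tissue phantom plants. An optional review mask
stands in for manual inspection. No size or shape filtering is applied:
the procedure is purely subtractive.

Volumes are voxel counts × voxel volume for whole brain, basal ganglia
and white matter; normalized by brain volume (GM + WM); natural-log
transformed. A zero whole-brain volume with the log requested is an
error — no pseudo-count is added, because a silent offset would distort
downstream regression coefficients; zero subregions yield NaN logs and
must be handled explicitly by the analyst.

Interrater reliability over paired volumes reports SEM
(SD of differences/√2), mean percent variability (|ΔV|/pair-mean × 100)
and ICC(2,1) via the two-way random-effects ANOVA formula (verified
against an independent implementation).

## Synthetic cohort generator

The generator defines the study conditions and emulates exactly the
statistical structure the battery assumes — so every model fit is a
parameter-recovery exercise, not a fit to arbitrary noise:

* **Design**: n = 120 subjects by default; annual MRI years 0–3, annual
  cognition years 0–5; baseline age N(70, 8²); 65% male.
* **Risk factors** (prevalences are this generator's stated choices,
  typical for a lacunar-stroke cohort): hypertension 0.85, diabetes 0.20,
  hypercholesterolemia 0.65, smoking current/ex/never 0.20/0.45/0.35,
  NART-IQ N(100, 12²).
* **ALPS trajectories**: baseline N(1.30, 0.15²) with loading 0.6 on a
  latent CSVD-severity factor that also drives WMH, lacunes,
  microbleeds, median MD and PSMD; fixed annual slope −0.010 with
  random-slope SD 0.005 and residual SD 0.02. Variance components are
  not published for the emulated models; these defaults are stated
  here, in config, and nowhere presented as estimates.
* **Cognition**: age-standardized z-scores (mean 0, SD 1 at baseline);
  per-subject linear slopes with mean −0.05 z/yr plus a per-domain
  coefficient on standardized baseline ALPS (global 0.030, executive
  0.060, memory 0.050, speed 0.010 z/yr per SD), slope SD 0.04,
  residual SD 0.30.
* **Dementia**: Weibull proportional hazards, H0(t) = scale·t^shape
  with shape 1.2 and log-HR −1.115 per SD of baseline ALPS (HR 0.328).
  The baseline scale is calibrated by root finding so the marginal
  5-year incidence equals 18.2%, where the marginal survival is
  evaluated by Gauss–Hermite quadrature over the standardized ALPS
  distribution; that same quadrature is the oracle the empirical event
  rate is tested against. Administrative censoring at 5 years.

What the generator does **not** emulate: realistic anatomy and partial
volume, scanner drift, missing visits, informative censoring, death as
a competing risk, and measurement error correlated across markers.
Passing tests therefore demonstrate correctness of the computations and
recoverability of parameters under the assumed models — not robustness
to real-data violations of those models.

## Statistical battery

* **Standardized β**: outcome and continuous predictors z-scored;
  binary covariates untouched; smoking enters as a 3-level categorical.
  The "vascular risk factors" covariate set is hypertension, diabetes,
  hypercholesterolemia, smoking; nested sets add NART-IQ, then visible
  CSVD markers (WMH, lacunes, microbleeds) or median MD or PSMD.
* **Mixed models**: random intercept + slope on time, ML (not REML)
  because fixed-effect p-values are reported. P-values are Wald
  normal approximations (the underlying library provides no
  Satterthwaite correction). The optimizer is Powell with a fallback
  chain; a singular random-effects covariance triggers a recorded
  fallback to random-intercept-only. Per-subject slopes are
  empirical-Bayes (BLUP) sums of fixed and random parts. With zero
  planted residual variance the ML optimum sits on the boundary of the
  variance space and the fixed slope is resolved to about 1e-5 in
  absolute terms — the tolerance used when tests call the noiseless
  case "exact".
* **Cox**: Efron tie handling (material with yearly visit schedules);
  HR per SD of the predictor when standardization is on; ≥5 events
  required.
* **FDR**: Benjamini–Hochberg, one family per results table (baseline,
  progression, cognition, dementia, marker change). The family
  definition is a choice, applied uniformly and visible in the output.
* **Cutpoint**: exhaustive search over midpoints of adjacent observed
  scores maximizing Youden's J; direction inferred from the sign of the
  score–event association; ties broken toward balanced groups, then the
  smaller cutoff. Optimal cutpoints are method-dependent; this is the
  midpoint/Youden convention.
* **Variable importance**: a standard random-forest regression with
  out-of-bag permutation importance (mean OOB squared-error increase
  per permuted feature, averaged over trees), seeded and deterministic.
  This is not a conditional-inference forest: correlated predictors
  share importance, which the output metadata notes. In-sample
  permutation was rejected because overfit trees assign noise features
  substantial in-sample importance.
* **Missing data**: listwise deletion with n reported per model; no
  imputation. Logistic fits detect complete separation and report
  non-convergence with no estimate rather than a diverging coefficient.

## Problem sizes and determinism

Default test/demo sizes — phantoms of ~1.3×10⁵ voxels × 58 volumes,
cohorts of 120–200 subjects for recovery checks, 1000 subjects for the
survival battery, 100 seeded replicates for CI coverage and importance
rankings — were chosen so each closed-form check is exact and each
stochastic recovery has comfortable power at desk scale. Every random
draw flows from an explicit integer seed through `numpy.random.default_rng`;
identical seeds reproduce every output bit-for-bit.

## Known limitations

* No eddy/motion correction, multi-shell or non-tensor models.
* PSMD is simplified: the skeleton is an input, not computed.
* Registration is consumed, never estimated; phantoms live in template
  space with identity transforms.
* The ROI orientation check flags but never relocates ROIs, whereas the
  manual workflow it replaces could move them.
* The interrater reliability routine implements the published metrics;
  whether such metrics fully characterize inter-observer PVS-volume
  error is left to the user's study design.
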