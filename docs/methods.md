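# Methods

`myodens` implements a complete analysis chain for muscle density (MusD)
from high-resolution peripheral QCT limb scans: soft-tissue segmentation,
sex-specific reference centile curves, subject-level standardised scores,
and the cohort statistics used to characterise predictors of MusD and its
relation to physical performance. Because no patient data ship with the
package, every stage is exercised against synthetic phantoms and cohorts
whose generating truth is known exactly.

## Soft-tissue segmentation

The pipeline follows the manufacturer-style soft-tissue evaluation for
second-generation HR-pQCT acquisitions (isotropic 60.7 μm voxels, 168
slices ≈ 10.2 mm of limb length):

1. **Filter and downscale.** A low-pass Gaussian (σ = 0.8 voxel, kernel
   support 1.0 voxel) is applied at native resolution, then the volume is
   block-mean downscaled 2× (60.7 → 121.4 μm). The order
   (filter-then-downscale) is not dictated by the procedure description;
   both orders pass the test suite and the order is a config switch
   (`filter_before_downscale`). Odd grid extents are padded by edge
   replication before blocking.
2. **Limb contour.** The largest connected component above an air
   threshold (default −700 HU, between subcutaneous fat and air),
   morphologically closed (ball radius 2, computed on an edge-replicated
   pad so stack faces are not eroded) and hole-filled.
3. **Skin peel.** The outer 20 voxels of the downscaled grid (≈ 2.4 mm)
   are removed. The distance transform is computed **per slice**
   (in-plane): skin is a radial annulus, so the first and last slices of
   the stack are not skin surfaces; a 3-D transform would peel the stack
   ends and, on short stacks, empty the interior entirely. A limb thinner
   than the peel everywhere yields an empty interior and a degeneracy
   flag rather than an error.
4. **Bone exclusion.** Interior voxels above 600 HU (the upper edge of the
   muscle seed window; configurable) are labelled bone — this also
   captures arterial calcifications — and excluded from all soft-tissue
   accounting.
5. **Seeding.** Muscle seeds where 100 ≤ HU ≤ 600; adipose seeds where
   −600 ≤ HU ≤ −200. Connected seed components (26-neighbourhood) with
   fewer than 50 voxels are returned to unclassified; the bound is strict
   (a 50-voxel component survives). Pruning is applied in 3-D.
6. **Iterative classification.** Ten rounds; in each round both classes
   dilate one voxel (face neighbourhood, so "one voxel per iteration" is
   literal) into unclassified soft tissue only. Skin, bone, background and
   already-settled voxels are never relabelled, which makes the muscle and
   adipose sets monotone non-decreasing across rounds. A voxel reached by
   both fronts in the same round is *contested* and is assigned by HU
   proximity to the two windows: at or above the midpoint of the gap
   between the windows (−50 HU) it becomes muscle, otherwise adipose.
   This rule is deterministic and orientation-independent; an
   independent brute-force per-voxel re-implementation reproduces the
   production classifier exactly on random 20³ volumes.
7. **Outcomes.** MusD = slope·mean(HU over final muscle voxels) +
   intercept, in mgHA/cm³; MV = muscle voxels × voxel volume; TV = all
   soft-tissue voxels inside the limb after skin and bone exclusion
   (muscle + adipose + still-unclassified); MV/TV in percent. Scaling the
   calibration (a, b) → (2a, 2b + c) maps MusD → 2·MusD + c exactly and
   leaves MV, TV and MV/TV untouched. Zero muscle voxels give MusD = NaN
   with a warning rather than an exception.

## Reference curves: the LMS / BCCG model

A positive outcome y at age t follows the Box-Cox Cole-Green (BCCG)
distribution with median μ(t), coefficient of variation σ(t) and Box-Cox
power λ(t):

    z = ((y/μ)^λ − 1) / (λσ)   (λ ≠ 0),    z = ln(y/μ) / σ   (λ = 0)

is standard normal. Centiles invert the transform:
C_α = μ(1 + λσ z_α)^{1/λ}. The implementation switches to the log branch
below |λ| = 1e−8 and is continuous there to better than 1e−6.

Each of λ, log μ and log σ is a cubic P-spline: an 8-function B-spline
basis on the observed age range with a second-order difference penalty on
the coefficients. The penalty null space contains constants and linear
trends, so arbitrarily heavy smoothing still fits a linear age drift — the
dominant pattern in adult MusD. Penalty weights are calibrated by
bisection so each curve spends a target number of effective degrees of
freedom (trace of the Gauss-Newton smoother matrix); defaults are 4 (μ),
2 (σ), 2 (λ), mirroring common LMS practice. All three coefficient
vectors are then optimised jointly with L-BFGS-B (analytic gradients,
box bounds for numerical safety) from fixed starts (λ ≡ 1, log μ from a
ridge fit to log y, log σ ≡ log(IQR/1.349/median)); weights and penalties
are recalibrated once at the optimum and the fit repeated. Everything is
deterministic: refitting identical data reproduces identical curves.

Fitting requires ≥ 50 records spanning ≥ 10 years; identical outcome
values are rejected as degenerate (σ → 0) and optimiser failure raises —
there is no silent fallback.

**What the fit can and cannot recover.** With n = 2000 and σ ≈ 0.05 the
median is recovered to better than 1% and σ to ~10%, and in-sample
z-scores are standard normal to ±0.05 in mean and ±0.1 in variance. λ,
however, carries Fisher information of order n·σ², i.e. a sampling SD near
0.5 at that design — λ is intrinsically weakly identified when the
coefficient of variation is small. This does not degrade z-scores or
centiles (μ and σ co-adapt), and at σ = 0.2 the same fitter recovers λ
within ±0.3. The exact smoothing engine of the original reference curves
(basis dimension, penalty selection) is not published, so numeric
replication of those curves is not attempted; the acceptance surface rests
on the printed regression coefficients instead.

## Scores

* **z-score**: Box-Cox transform at the subject's age; percentile =
  100·Φ(z). Ages outside the fitted range are refused, never extrapolated.
* **t-score**: transform evaluated at the anchor age a*, the grid argmax
  of the fitted median curve (ties resolve to the smallest age). When a
  subject's age equals a*, t = z identically.
* **Modified scores**: the LMS transform compresses extreme values, so for
  scores above +2 the deviation from the median is re-expressed in units
  of half the distance between the median and the +2 centile (growth-chart
  convention). Modified t uses the same construction anchored at a*. A
  symmetric option extends the rule below −2 (severe deficits face the
  same compression) but is off by default to match reporting convention.
* Ages from dates use (scan − birth)/365.25.

Batch scoring returns one row per input row with an error code on rows
that cannot be scored (unknown sex, out-of-range age, non-positive value);
rows are never silently dropped.

## Cohort statistics

* OLS through statsmodels' formula interface; sex, race and ethnicity are
  treatment-coded against male / White / non-Hispanic. "Adjusted p" is the
  covariate-adjusted p-value from the multivariable model; no
  multiple-testing correction is applied. Complete cases per model; the
  base and MusD-augmented performance models share one row set even when
  MusD has extra missingness.
* VIF_j = 1/(1 − R²_j) from explicit auxiliary regressions; perfect
  collinearity reports as infinity. The conventional cut-off of 10 is
  applied by the analyst, not automatically.
* Pain exclusion: grip and sit-to-stand values are nulled when the
  matching pain rating exceeds 3/10 (strict: 3 is retained). Ratings
  outside 0–10 invalidate that row's value with an `invalid_pain` reason.
  The filter is idempotent and logs counts per test and sex.
* RMS-CV: per subject CV_i = 100·SD_i/mean_i (sample SD, ddof = 1);
  RMS-CV = √(mean CV_i²). Scale-invariant by construction.
* Cohort comparison: one-sample t-test of z-scores against 0 with a
  symmetric 95% CI; zero variance with nonzero mean reports t = ±∞ as a
  boundary case.

## Synthetic data

**Phantoms** are concentric-annulus limbs (air | skin | subcutaneous fat |
muscle compartment | circular bone inclusions) extruded along the scan
axis at 60.7 μm. Tissue means default to muscle 300 HU, fat −300 HU, bone
1500 HU, skin 20 HU, air −1000 HU — chosen to sit safely inside the
respective classification windows — with additive Gaussian noise (default
10 HU; 15 HU in the stress tests). A fraction f of muscle-compartment
voxels carries fat HU, placed voxel-wise at random by default or clustered
into blobs for dilation stress tests. Ground truth records the exact label
array, voxel counts (volumes are counts × voxel volume, exactly) and the
noiseless calibrated mean over the muscle compartment. The default
calibration (0.08 mgHA/cm³ per HU, intercept 0) is a synthetic convenience
mapping the 300 HU muscle default to a realistic MusD of 24 mgHA/cm³.
Phantoms do **not** emulate scanner physics: no beam hardening, local
tomography or motion artefacts, and no realistic muscle anatomy — so
passing tests demonstrate correctness of the segmentation logic, not
robustness to acquisition artefacts.

**Cohorts** draw per-sex covariates (height, BMI, whole-body % fat,
ALM/height²) from normal distributions whose locations are the
participant-weighted per-decade medians of the published reference cohort
and whose SDs convert the printed interquartile ranges via IQR/1.349.
Race and ethnicity follow the published per-sex frequencies. Weight is
BMI·height² exactly, which reproduces the height/weight/BMI collinearity
that the VIF screen must flag. Covariates are otherwise independent per
sex; a BMI↔%fat correlation knob exists for collinearity demonstrations.
MusD at each site is the published multivariable linear combination of the
covariates (height in cm) plus a Normal(0, 1.3 mgHA/cm³) residual. The
printed tables include no intercept, so the intercept anchors the
predicted MusD of a reference male (pooled male median covariates, age
23.5, White, non-Hispanic) to the young-male decade median (24.75 forearm,
25.64 leg mgHA/cm³). Performance outcomes are base-covariate linear
models (coefficients are package defaults chosen to land near the
published per-sex medians) plus the published MusD term; the residual SD
is solved at generation time so the base covariates explain the published
variance fraction (e.g. ~0.648 for grip strength). Sit-to-stand counts
are left continuous so the generating model stays exactly linear. Pain
ratings are 0 for most subjects with ~10% mild (1–3) and ~5% above the
exclusion threshold. The per-decade generator draws ages uniformly within
each decade and outcomes Normal(decade median, dispersion); the published
parenthetical ranges may be IQRs or CIs of the median, so dispersion is an
explicit parameter (0.6 mgHA/cm³ in the examples) rather than a value
derived from either reading.

A cohort generated this way is a *linear-model idealisation*: real
covariates trend with age and correlate with each other, and real MusD
residuals need not be Gaussian or homoscedastic. Recovery tests therefore
validate the estimation machinery, not the biology.

## Problem sizes and budgets

Test phantoms are 260×260×8–16 voxels (a scaled-down in-plane extent at
the native voxel size), large enough that boundary partial-volume effects
stay below the 5% muscle-volume tolerance. Parameter-recovery fits use
n = 2000 (LMS) and n = 5000 (regressions, matching the acceptance
targets); unbiasedness uses 40 replications at the reference-cohort size
n = 1662. The full suite runs in well under a minute on one CPU;
`scripts/acceptance.py` takes a few seconds.

## Known limitations

* Segmentation order-of-operations details of the proprietary evaluation
  script (alternate vs simultaneous dilation, HU gating of dilated voxels,
  2-D vs 3-D pruning) are not public; the choices here (simultaneous
  fronts, contested-voxel HU rule, 3-D pruning) are documented and
  configurable where reasonable.
* λ(t) is weakly identified at small coefficients of variation (see
  above); its fitted values should not be interpreted tightly.
* Reference scores refuse ages outside the fitted range rather than
  extrapolating; cohorts with many subjects outside 18–80 y cannot be
  scored against the default curves.
* MusD cannot separate inter- from intramuscular fat, and the synthetic
  cohort's performance models are structural stand-ins, not re-estimates
  of the published base-model coefficients (only the MusD terms and
  variance fractions are published).
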