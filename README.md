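# myodens

Muscle density (MusD) analysis for limb CT, end to end: soft-tissue
segmentation of HR-pQCT-style volumes, sex-specific LMS (Box-Cox
Cole-Green) reference centile curves over age, a calculator for
subject-level percentiles and z-/t-/modified scores, and the cohort
statistics used to study predictors of MusD and its relation to physical
performance. Seeded synthetic phantoms and cohorts make the whole chain
testable without any patient data.

**Who it is for.** Researchers working with peripheral QCT soft-tissue
outcomes who need (a) a transparent, tested re-implementation of the
seeded iterative muscle/adipose segmentation, (b) reference-curve fitting
and standardised scoring for normative studies of muscle composition, or
(c) a simulation bench for the statistical analyses around them.

## The model in brief

CT attenuation inside the segmented muscle compartment, calibrated to
hydroxyapatite density, gives **MusD** (mgHA/cm³) — lower values mean more
fat-infiltrated muscle (myosteatosis). The segmentation filters
(Gaussian σ 0.8), downscales 2× (60.7 → 121.4 μm), contours the limb,
peels the outer 20-voxel skin layer, excludes bone (> 600 HU), plants
muscle (100–600 HU) and adipose (−600 to −200 HU) seeds, deletes seed
islands under 50 voxels, and grows both classes for 10 one-voxel
dilations; it reports MusD, muscle volume (MV), total soft-tissue volume
(TV) and MV/TV.

Reference curves model MusD at age t by the BCCG distribution with smooth
curves λ(t), μ(t), σ(t) (penalised-likelihood P-splines), so that

    z = ((y/μ(t))^λ(t) − 1) / (λ(t) σ(t))

is standard normal. Percentile = 100·Φ(z); t-scores use the parameters at
the age a\* where the median curve peaks; scores above +2 get modified
scores in units of half the median→+2-centile distance. Cohort analyses
are multivariable OLS with VIF collinearity screening, pain-based
exclusion of performance tests (> 3/10), RMS-CV precision and one-sample
t-tests of cohort z-scores.

## Worked example

`examples/segment_phantom.py` builds a noisy limb phantom with 20%
intramuscular fat and runs the full pipeline:

```
ground truth : MV = 0.0429 cm^3, mean muscle density = 14.40 mgHA/cm^3
segmentation : MV = 0.0427 cm^3, TV = 0.0699 cm^3, MV/TV = 61.1 %, MusD = 14.17 mgHA/cm^3
MV error     : -0.59 % (muscle volume recovered from a noisy, fat-infiltrated phantom)
repeat 'scans': MusD RMS-CV = 0.13 %, MV/TV RMS-CV = 0.07 % (short-term precision across three noisy re-instantiations)
```

The segmented muscle volume lands within 0.6% of the phantom's exact
compartment volume, and the segmented MusD (14.17) sits just below the
noiseless compartment mean (14.40) because boundary voxels blend with
neighbouring fat. `examples/fit_reference_curves.py` fits the centile
curves to a decade-structured synthetic cohort:

```
sex F: median peaks at 24.14 mgHA/cm^3 (age 21.2 y), average decline 0.64 mgHA/cm^3 per decade
sex M: median peaks at 25.75 mgHA/cm^3 (age 20.2 y), average decline 0.68 mgHA/cm^3 per decade
```

— the median is highest at the young end and declines with age, as leg
MusD does. `examples/score_subjects.py` scores subjects against such a
model (median → z = 0, percentile 50; a low value → strongly negative z; a
value above the +2 centile → flagged with a modified score), and
`examples/cohort_analysis.py` reproduces the statistical chain: the VIF
screen flags weight (VIF ≈ 131) until it is dropped, the multivariable
model recovers the sex and age coefficients of the MusD generating model,
and the grip-strength model recovers a positive forearm-MusD term over and
above the base covariates.

## Layout

- `src/myodens/` — `segmentation` (pipeline), `lms` (BCCG fitting and
  transforms), `calculator` (scores), `cohort_stats` (regressions, VIF,
  RMS-CV, cohort tests), `phantoms` / `cohorts` (synthetic data),
  `reference_tables` (published normative constants), `volume` (CT
  container + NIfTI I/O).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model details, numerical choices, design decisions
  and limitations.
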