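# Methods

`tucoda` analyses how the composition of the 24-hour day — sleep,
sedentary time (SED), light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA) — changes across a life
transition such as retirement, in a two-wave accelerometer cohort.
This note records the models, the detector rules, the synthetic-data
assumptions and the numerical choices, in the package's own terms.

## The compositional model

A day is a 4-part composition `x = (sleep, SED, LPA, MVPA)` closed to a
constant `κ` (1 or 1440 min). Only ratios carry information, so all
statistics live in Aitchison geometry:

* **Closure** `C(x) = κ·x / Σx`.
* **Perturbation** `x ⊕ y = C(x·y)`, the group operation; the change
  from wave 1 to wave 2 is the perturbation difference
  `C(post / pre)`, with neutral element `(¼,¼,¼,¼)`.
* **Compositional mean**: closure of component-wise geometric means.
* **Zero replacement**: a device cannot resolve very small MVPA, so a
  zero part is imputed multiplicatively at 65% of a 1-minute detection
  limit and the remaining parts are scaled by `(κ − Σδ)/κ`,
  preserving the total and all ratios among nonzero parts. Both the
  fraction and the limit are arguments of `replace_zeros`.

### Balance coordinates

The isometric log-ratio (ilr) transform used throughout is the balance
basis of a sequential binary partition (SBP):

| coordinate | positive group | negative group | reading |
|---|---|---|---|
| z1 | LPA, MVPA | sleep, SED | active vs passive behaviors |
| z2 | LPA | MVPA | LPA vs MVPA |
| z3 | SED | sleep | SED vs sleep |

with `z_k = sqrt(r·s/(r+s)) · ln(g(x₊)/g(x₋))` for group sizes `r`, `s`
and geometric means `g`. `SequentialBinaryPartition` validates
nestedness at construction and exposes the orthonormal contrast matrix
`V` (`z = V ln x`); the inverse is `C(exp(Vᵀ z))`. The kernels accept
any number of parts; the 4-part partition above is merely the default.

## Accelerometer-epoch processing

The processing stage consumes 5-s epoch summaries (ENMO in mg, arm
angle in degrees, per-axis SD and range of the surrounding 60-min
window) plus a daily diary of bed and waking times:

* **Non-wear**: 15-min blocks; a block is non-wear when ≥2 of 3 axis
  SDs are < 13 mg or ≥2 of 3 axis ranges are < 50 mg in its 60-min
  window. The window statistics are carried on the epoch records (the
  raw 80 Hz stage is out of scope); each block is judged from the epoch
  at its centre, so non-wear resolves at 15-min granularity.
* **Sleep**: within the diary window only, maximal spans ≥ 5 min over
  which the arm angle stays inside a 5° band. A posture change starts
  a new span; adjoining calm spans merge, so an uninterrupted night of
  several postures is one interval. No restriction on night duration.
* **Intensity**: SED < 30 mg ≤ LPA < 100.6 mg ≤ MVPA, boundaries
  closed exactly as stated.
* **Days**: bedtime to next bedtime; a day is valid with ≥ 600 min
  waking wear; a participant is kept only with ≥ 4 valid days at both
  waves. Non-wear during the diary window counts as non-wear, not
  sleep (conservative choice). Partition identity: sleep + SED + LPA +
  MVPA + non-wear = day length, to epoch resolution.

## Synthetic cohort

The generator emulates a two-wave occupational cohort: four
gender-by-occupation strata of 308/164/54/25 participants (551 total),
seven days per wave, one year between waves. Group pre-wave means and
the post-wave change perturbations default to the published group
summary values. Noise is logistic-normal — participant effects `b_i`,
participant change effects `s_i` and day effects `e_{ij}` are
independent normals in 3-D balance space:

    z_ij(pre)  = z(mean) + b_i + e_ij
    z_ij(post) = z(mean) + z(perturbation) + b_i + s_i + e_ij'

mapped back through the inverse ilr and rescaled to the day length.
Because the transform is log-linear, the group compositional means are
exactly the configured means, and the post-vs-pre perturbation
difference of the means converges to the configured perturbation.

The day-to-day and between-person variance magnitudes are not published
for the cohort being emulated; the defaults — between-person SD
(0.30, 0.35, 0.18), day-level SD (0.25, 0.40, 0.20), change SD
(0.15, 0.20, 0.10) per coordinate — are this package's own choice of
plausible magnitudes for wrist-worn data (day-level spread larger for
the LPA/MVPA balance, smallest for the stable SED/sleep balance). Six
person-days are forced to exactly zero MVPA to exercise zero
replacement, and ~1.5% of days are made invalid to exercise the
validity filter, mirroring observed compliance. Days default to
exactly 24 h; a day-length jitter option exists but is off.

The epoch simulator realises a target day composition on the epoch
grid (sleep pinned to the diary window, waking behavior in shuffled
5-min bouts with ENMO drawn inside the correct band, calm posture
segments of 30–60 min during sleep) and can inject constant-signal
non-wear blocks aligned to the 15-min detector grid. What it does
*not* emulate: transitional epochs straddling cut-points, autocorrelated
intensity within bouts, naps outside the diary window, gradual non-wear
onset. Round-trip tests therefore demonstrate the internal consistency
of detectors and accounting, not the field accuracy of the cut-points.

## Mixed models

Each balance coordinate is modelled separately:

    z_k ~ time + gender + occupation            (model 1)
        + time:gender + time:occupation         (model 2)
        + time:gender:occupation + lower terms  (model 3)

with a random intercept and random slope of time per participant,
estimated by REML (statsmodels `MixedLM`), Wald 95% CIs and p-values.
Coding: time post = 1; reference categories woman and non-manual, so a
positive occupation effect on z1 means manual workers are more active
at baseline. Model 2 optionally adds the static gender×occupation
term (`model2_gender_occupation=True`); the default follows the
time-interaction reading.

Aggregation: the default fits every valid day (`day_level`); with only
two waves, day-level replication is what makes the random-slope
variance identifiable. `wave_mean` collapses each participant-wave to
its compositional mean first — for log-ratio coordinates the ilr of the
geometric mean equals the mean of the day ilrs — and then only a random
intercept is estimable (two observations per participant); the fit
drops the slope automatically. Non-convergence triggers an
intercept-only refit and is flagged on the results object. At the
zero-variance boundary (noise-free data) the optimizer reports
non-convergence while the fixed effects are exact; tests assert the
estimates and the flag separately.

## Descriptive output and geometry

The descriptive table reports, per group and wave, compositional means
rescaled to 1440 min and a change block of after-minus-before
differences rounded to whole minutes. Changes are computed from
unrounded means and then rounded (default); this is why a change cell
can differ by one minute from subtracting two independently rounded
means. The rounded-then-subtract convention is available.

Ternary geometry works on the four leave-one-out triples of the 4-part
composition. Confidence regions for a group mean: bootstrap the
compositional mean (which in balance coordinates is the arithmetic mean
of the resampled coordinates), assume normality in the 2-D log-ratio
plane of the triple's own SBP (first part vs rest, then second vs
third — any orthonormal basis gives the same ellipse), and trace the
Mahalanobis ellipse at the χ²₂ quantile with 128 boundary points,
mapped back to the simplex. A degenerate bootstrap covariance
collapses the region to a point. Bootstrap covariance slightly
understates the sampling variance at small n, so empirical coverage
sits a shade under nominal (~94% at n = 100, B = 200), within the
tolerance the tests assert.

Outlier screening summarises each participant's change by the six
pairwise log-ratio change scores `ln((post_i/post_j)/(pre_i/pre_j))`
and flags a participant when any score's robust z (median/MAD, MAD
scaled by 1.4826) exceeds 3.5. No numeric rule is published for this
screen (the original screen was by inspection); 3.5 is a conventional
robust-z cutoff, configurable, and flagged participants are reported
in an artifact rather than silently dropped.

## Problem sizes and determinism

Every stochastic routine takes a seed; cohort simulation derives
per-stratum child seeds from a `SeedSequence`, so output is
reproducible and independent of chunking. The test suite and the
acceptance script size their simulations to desk scale: parameter
recovery uses 500 participants per stratum × 7 days (one fit),
interval calibration 200 replicates of 500 participants fitted on wave
means, region coverage 500 replicates of 100 samples with 200
bootstrap draws, epoch round trips 50 days at 5-s resolution.

## Known limitations

* The epoch simulator's signal model is schematic (see above); it
  validates rules, not physiology.
* Wave-mean fits cannot separate participant-change variance from
  residual variance; day-level fitting is the default for exactly this
  reason, and which aggregation the original analysis used is not
  asserted.
* The outlier screen's threshold is a convention, not an estimate.
* The processing stage assumes a regular epoch grid and rejects gaps
  rather than imputing them.
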