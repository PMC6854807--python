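# Methods

This note documents the models, conventions, numerical choices and
limitations of `gehroc`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Axis and angle conventions

All vector quantities use one fixed orthogonal frame: **X** right→left,
**Y** superior→inferior (positive down), **Z** anterior→posterior (positive
back). Amplitudes are μV throughout; sampling is 500 Hz unless stated.

- **Azimuth** of a vector is `atan2(z, x)` in degrees, range (−180°, 180°]:
  0° points left (+X), +90° points back (+Z). A quadrant-aware arctangent is
  used deliberately — a plain two-argument ratio `arctan(z/x)` cannot
  distinguish front from back, and the SVG azimuth must span both.
- **Elevation** defaults to the geometric polar angle from the +Y axis,
  `atan2(hypot(x, z), y)`, range [0°, 180°] (0° = straight down,
  90° = horizontal, 180° = straight up). Some reports print the
  two-component form `arctan(x/y)`; that "literal" variant, range
  (−90°, 90°), is available via `elevation(..., mode="literal")` and the
  `--elevation-mode` CLI flag. Results should state the mode; the default is
  the conventional one because it is the quantity a 3-D loop display shows.
- Spatial angles are `arccos` of the normalized dot product, clamped to
  [0°, 180°]; zero-magnitude inputs are an error, not a silent 0.

## Kors transform

X, Y, Z are fixed linear combinations of the 8 independent standard leads
(I, II, V1–V6) using the Kors et al. (1990) regression coefficients, stored
verbatim as `vcg.KORS_MATRIX`. The limb-derived leads III, aVR, aVL, aVF are
redundant and ignored. Missing or non-finite leads raise an error naming the
lead.

## Median beat and origin point

Beats labelled `pvc`, `pre_post_pvc` or `noisy` never contribute. At least
three usable normal-sinus beats are required. Each usable beat is windowed
on a grid spanning the median RR interval with the R peak at 35% of the
window (enough pre-QRS samples for origin detection, enough post-QRS for the
T wave). Beats are aligned by maximizing the cross-correlation of each
beat's spatial vector magnitude against the running median template
(integer shifts up to ±10 ms, one refinement pass), then reduced by a
per-sample median. The aligned median can carry a global time offset of a
sample or two relative to any individual beat; fiducial-based windows are
wide relative to this, so metrics are unaffected.

The heart-vector origin is the mean XYZ over the flattest 20 ms window —
minimum mean absolute spatial velocity — inside [QRS onset − 40 ms,
QRS onset], and is subtracted componentwise. This is a declared
simplification of the published origin-point algorithm (which this package
does not reproduce); it is exact for constant baseline offsets and reduces
slow drift.

## Windows and integration

QRS quantities use [QRS onset, QRS offset]; T quantities use
(QRS offset, T offset], half-open at the shared boundary so the boundary
sample is not counted twice. Peak vectors are the XYZ sample of maximal
vector magnitude in the window, ties resolved to the earliest sample. Area
vectors and SAI QRST integrate by the trapezoidal rule on the native
sampling grid with dt in ms; area units are μV·ms (SAI QRST converted to
mV·ms). No time normalization is applied to area magnitudes — whether
"mean" vectors should be time-averaged is genuinely ambiguous in the field;
angles are unaffected either way and magnitudes are reported with explicit
units.

## Synthetic ECG generator

The generator synthesizes an XYZ dipole as two Gaussian-windowed lobes
(QRS, T) whose spatial peak vectors equal the requested
(azimuth, elevation, magnitude) exactly at the lobe centers. Lobe σ is
duration/6, so ±3σ lies inside the fiducial windows and the pre-QRS origin
region is numerically flat. The dipole is mapped to the 8 independent leads
through the Moore–Penrose right-inverse of the Kors matrix — guaranteeing
that the Kors transform recovers the dipole to numerical precision, so the
measurement chain is exercised end-to-end, not mocked — and the four limb
derived leads follow from the standard relations (III = II − I, etc.).
PVCs are wide (1.5× duration), large (1.5× magnitude), QRS-reversed lobes
without a T wave; their neighbouring sinus beats are labelled
`pre_post_pvc`. White noise and a 0.33 Hz sinusoidal baseline wander with
random per-lead phase are optional.

`meta["ground_truth"]` stores the GEH values measured directly on the clean
single-beat dipole — the reference the full 12-lead chain is validated
against (angles within 1°, magnitudes within 1% in the acceptance suite).

What the generator does **not** emulate: P waves, physiological QRS/T
morphology beyond smooth lobes, respiration coupling, RR variability,
electrode misplacement. Passing tests therefore demonstrate correctness of
the vector geometry pipeline, not robustness to every artifact of clinical
recordings.

## Synthetic cohort generator

Each participant: standard-normal baseline marker `z`; covariates drawn to
mirror a mid-1980s US atherosclerosis cohort (age ~ N(54.2, 5.8²), 55%
female, 73% white, 12% diabetes, 35% hypertension, 4.8% CHD, 1.7% stroke);
two cause-specific exponential event times with hazards
`λ_c · exp(β_c z + Σ γ_j x_j)` (same covariate effects γ on both causes,
age standardized); independent exponential loss to follow-up; and
administrative censoring. Follow-up ends at the earliest of these; the
event code (0 censored / 1 SCD / 2 non-SCD) is its cause. Visits occur
every `visit_spacing` years while the participant remains under follow-up;
the marker drifts across visits as a random walk (the longitudinal marker
process of the real cohorts is not published; the random walk is a
stand-in that produces the repeated-measures structure the partition scheme
needs, not an estimate). Hazards are driven by the baseline marker; visit
records reuse the participant's event time measured from each visit's ECG.

Defaults are the study-scale conditions: baseline SCD hazard 1.76/1000
person-years, non-SCD 2.55/1000, administrative censoring at 25 years,
5 visits spaced 3 years, loss to follow-up 5/1000 person-years (a modest
rate chosen to keep most follow-up informative), marker drift SD 0.1 per
visit, `β_SCD = 0.7`, `β_nonSCD = 0` — the latter two encode the
"SCD-specific marker" scenario that the specificity analyses test.

A separate single-visit **binormal** generator gives cohorts with a known
true AUC: cases (event inside the horizon) draw markers from N(δ, 1),
controls from N(0, 1), so the cumulative/dynamic AUC is exactly
Φ(δ/√2) (`binormal_true_auc`), with optional independent exponential
censoring.

## Nearest-neighbor ROC(t)

Cumulative-case / dynamic-control ROC at horizon t. The bivariate survival
`S(c, t) = P(M > c, T > t)` is estimated as the average over subjects of a
Kaplan–Meier computed in each subject's marker-rank neighborhood: a
contiguous window holding a fixed fraction (the span) of the sample,
shifted — not truncated — at the rank boundaries so every neighborhood has
the same size (minimum 2). Sensitivity and specificity follow as

```
sens(c) = [P(M > c) − S(c,t)] / [1 − S(t)],   spec(c) = [S(t) − S(c,t)] / S(t)
```

evaluated on the grid of unique marker values, clipped to [0, 1]. Because
the raw estimator need not be monotone, the curve is repaired by a
cumulative max before trapezoidal integration (repair count retained on the
curve object). Horizons with no observed events raise an explicit
"inestimable" error rather than returning a default.

The default span is the `0.25·∛n` **percent** rule applied to the records
in the analysis set at hand. This differs from the `0.25·n^(−1/5)`
convention of the estimator's reference implementation; both are available
(`span_rule="cbrt"` / `"classic"`), the percent rule is the default. The
row-wise KM is fully vectorized (sliding windows + per-row argsort), which
is what keeps the 500-replicate bootstrap affordable.

## Partitioning, bootstrap, aggregation

Records are divided into 5 disjoint partitions with each participant at
most once per partition; participants with 5 visit records contribute one
to every partition (random visit→partition assignment), fewer-visit
participants go to a random subset. The bootstrap resamples participants
(not records) with replacement within a partition — within a partition each
participant has one record, but the participant-level resampling contract
is kept for generality — and the 95% CI is the 2.5/97.5 percentile interval
(no BCa correction; none is claimed). Replicates inestimable at a horizon
are skipped and counted. Per horizon, the point estimate and both CI bounds
are averaged across the partitions that are estimable there.

All stochastic operations take explicit seeds; a single seeded generator
inside `evaluate_marker` derives per-partition and bootstrap seeds, so a
run is reproducible from one integer.

## Expected CI width

Hanley–McNeil (1982): `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`,
`var = [A(1−A) + (n₁−1)(Q1−A²) + (n₂−1)(Q2−A²)]/(n₁n₂)`; width
`2·z₀.₉₇₅·SE` with the z quantile at full double precision (1.959964…;
rounding z to 1.96 reproduces the same 3-decimal values). Bounds are
symmetric and deliberately unclipped — an upper bound near or above 1 at
11 events is the informative statement about power. This variance
approximation reproduces the full published 72-row predicted-width grid to
within ±0.002 (verified in the test suite); the originating software's
internal method is not documented, so the equivalence is empirical.

## Landmark windows and reclassification

Windows: 1–90, 91–180, 181–365, 365–730, 731–1825 days, and >5 years.
Risk-set construction is the standard landmark choice (the source analyses
do not state theirs): subjects with follow-up ≥ window start are at risk;
events of the target type inside the window are cases; subjects whose
follow-up ends inside the window otherwise (loss or competing death) are
dropped. High-risk threshold 25% for the three windows within the first
year, 10% beyond.

Logistic fits use Newton–Raphson (statsmodels) with tolerance 1e-8, max 50
iterations; constant predictor columns are dropped (absorbed by the
intercept); |coefficient| > 15 triggers a separation warning and flags the
result. Probabilities are in-sample. IDI is the difference in
discrimination slopes; category-free NRI counts any probability movement;
p-values are Pencina's asymptotic z-tests. No censoring-weighted
(survival-NRI) variants and no optimism correction are provided.

## Problem sizes in the test suite

The acceptance tests run the statistical experiments at sizes that give
stable conclusions in a routine CI budget: oracle equivalence on 50 cohorts
of 100–200 subjects; binormal parameter recovery over 20 seeds at n = 2000
with B = 200; SCD-specificity over 10 seeds at n = 4000 (point estimates,
no bootstrap); GEH recovery over a 100-point geometry grid; reclassification
null calibration over 200 replicates at n = 2000. The oracle-equivalence
cohorts start at n = 100 because below that the minimum rank-window (2
observations) makes the estimator's smoothing bias comparable to the 0.02
equivalence tolerance — a small-sample property of the estimator itself.

## Known limitations

- Fiducial points and beat labels are inputs; the package does not delineate
  raw waveforms or detect R peaks.
- Bazett is the only QT correction.
- Cause-specific censoring of the competing death, not Fine–Gray
  subdistribution modelling; the reported quantities are cause-specific
  accuracies.
- The origin-point detector is a simplification (see above).
- Incident/dynamic ROC(t), covariate-adjusted AUC, and survival-NRI are out
  of scope.
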