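# gehroc

Global electrical heterogeneity (GEH) electrocardiographic markers and their
**dynamic predictive accuracy** for competing mortality outcomes — sudden
cardiac death (SCD) versus non-sudden cardiac death (non-SCD) — evaluated in
a censored-survival framework.

The package is aimed at cardiovascular epidemiologists and ECG-methods
researchers who want to (a) compute vectorcardiographic GEH markers from
standard 12-lead ECGs and (b) ask, for any continuous biomarker measured in a
longitudinal cohort, *how well does it predict an event within t months or
years of the recording*, and how that accuracy decays or persists with the
horizon.

Because the motivating epidemiological cohorts are access-restricted, the
package ships a first-class synthetic-data module: a dipole-model 12-lead ECG
generator with exactly controllable QRS/T spatial loop geometry, and a
competing-risk longitudinal cohort generator with known marker–hazard links.
Every analysis stage is validated against these known ground truths.

## What it computes

**GEH markers** (from a 12-lead ECG):

- The 8 independent leads (I, II, V1–V6) are projected onto orthogonal
  X, Y, Z leads with the Kors regression matrix.
- A time-coherent normal-sinus **median beat** is built (PVCs, their
  neighbouring sinus beats, and noisy beats excluded; alignment by
  cross-correlation of the spatial vector magnitude), and the heart-vector
  **origin point** is subtracted (flattest 20 ms pre-QRS window).
- From the corrected beat: spatial **peak** and **area** QRS and T vectors,
  the spatial QRS–T angle
  `θ = arccos( Q·T / |Q||T| )`,
  the spatial ventricular gradient `SVG = Q + T` with its azimuth,
  elevation and magnitude (peak form and Wilson/area form), the scalar
  `SAI QRST = ∫|X| + ∫|Y| + ∫|Z|` over QRS-onset→T-offset, plus heart
  rate, QRS duration, and Bazett-corrected QT.

**Time-dependent ROC(t) AUC** (cumulative cases / dynamic controls) with the
nearest-neighbor bivariate survival estimator of Heagerty–Lumley–Pepe, which
lets censoring depend on the marker. Neighborhood span `0.25·∛n` percent of
the observations. Five non-overlapping cohort partitions (each participant at
most once per partition; a participant with five visit ECGs contributes one
to each), a 500-replicate percentile bootstrap per partition, and averaging
of point estimates and CI bounds across partitions. Competing deaths are
censored at their time (cause-specific accuracy).

**Expected CI width** for an AUC at a given events/non-events split, from the
Hanley–McNeil (1982) variance — the analytic power benchmark against which
observed bootstrap CIs are compared.

**Reclassification**: logistic clinical risk model (age, sex, race, diabetes,
hypertension, CHD, stroke) ± one ECG marker per landmark outcome window, with
absolute IDI, category-free NRI, and two-category NRI (high risk ≥ 25% for
windows up to 1 year, ≥ 10% beyond).

## Worked example

Expected precision of an AUC estimated from 11 events among 15,716 subjects:

```
$ geh power --auc 0.809 --events 11 --nonevents 15705
AUC 0.809  events 11  non-events 15705
SE 0.0793  95% CI width 0.311  bounds (0.654, 0.964)
```

With only 11 events, even an observed AUC of 0.81 carries a predicted 95% CI
about 0.31 wide — short-horizon prediction is power-limited regardless of the
marker.

Dynamic accuracy of a marker in a synthetic cohort (2,000 participants, up to
5 triennial visits, SCD log-hazard 0.7 per marker SD):

```python
from gehroc import SurvGenParams, generate_cohort, evaluate_marker
from gehroc.survival_auc import summaries_to_frame

cohort = generate_cohort(SurvGenParams(n_participants=2000, seed=42))
s = evaluate_marker(cohort, "marker", outcome="SCD",
                    horizons=(2.0, 5.0, 10.0), B=100, seed=7)
print(summaries_to_frame(s, "marker", "SCD")
      .query("partition=='aggregate'").round(3).to_string(index=False))
```

```
marker outcome  horizon partition   auc  auc_lb  auc_ub  n_events
marker     SCD      2.0 aggregate 0.709   0.504   0.880        42
marker     SCD      5.0 aggregate 0.721   0.604   0.819       106
marker     SCD     10.0 aggregate 0.727   0.655   0.800       198
```

The aggregated AUC ≈ 0.71–0.73 matches the binormal expectation
Φ(0.7/√2) ≈ 0.69 for this hazard link, and the CI narrows as events
accumulate at longer horizons — the power effect quantified by `geh power`.

An end-to-end run (simulate → GEH → ROC(t) → power → reclassification →
figures + manifest):

```bash
geh all --n 2000 -B 500 --seed 7 --out my_run
```

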