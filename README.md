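# cd4slope

Does the *rate* of CD4 decline before antiretroviral therapy tell you
anything about a patient's prognosis once therapy starts?  Treatment
guidelines of the late 2000s suggested initiating combination
antiretroviral therapy (cART) early in patients whose CD4 count was
falling faster than ~100 cells/µl per year.  `cd4slope` implements, as a
tested and reusable pipeline, the cohort analysis that interrogates this
idea in HIV seroconverters — people whose infection date is bracketed by a
last-negative and first-positive antibody test — and exercises every stage
on synthetic cohorts, so no patient data are needed.

The package is aimed at biostatisticians and epidemiologists who want to
reproduce, probe, or extend this style of prognostic-marker analysis:
longitudinal biomarker modelling, shrinkage estimation of per-patient
slopes, informative-censoring corrections, and survival models with
discrimination assessment.

## What it computes

**Per-patient CD4 slopes** (cells/µl per year) by three competing methods:

- *two-point*: interpolation of the last two counts ≥ 6 months apart;
- *OLS*: per-patient least squares on all counts;
- *BLUP*: best linear unbiased predictions from a linear mixed model with
  patient-specific random intercept `b0i` and random slope `b1i`,

  `CD4_ij = β0 + b0i + (β1 + b1i) t_ij + ε_ij`,

  which shrink each patient's slope toward the population slope β1 in
  proportion to how little data the patient has.

**Trajectory models.** Beyond the linear mixed model, an integrated
Ornstein–Uhlenbeck (IOU) model

`CD4_i(t) = β0 + b0i + β1 t + W_i(t) + ε`,  `W_i(t) = ∫0^t v_i(s) ds`,

where the velocity `v_i` is a stationary OU process with mean-reversion
rate α and stationary SD τ.  α measures how stable a patient's slope is:
α → 0 recovers the constant-slope mixed model; α → ∞ (with σ²/α² fixed)
gives Brownian wandering around the population slope, under which the
slope autocorrelation `exp(-α·lag)` vanishes within months.  Models are
compared by AIC on square-root-transformed counts, and α gets a
profile-likelihood confidence interval whose upper limit may be reported
as unbounded.

**A joint model** couples the mixed model with a proportional-hazards
model for time to cART initiation whose linear predictor loads on
`(b0i, b1i)` — a shared-random-effects correction for series truncated
because low-CD4 patients start therapy.

**Outcome models.** Stratified Cox regression (strata: baseline CD4
category <100 / 100–<200 / 200–<350 / ≥350 cells/µl × injection-drug-use
transmission; covariates: slope, log10 viral load, age, prior AIDS) for
time from cART initiation to a new AIDS event or death, hazard ratios per
+10 cells/µl/yr of slope, event rates per 100 person-years, Harrell's
c index of 5-year risk predictions, and slope-quartile event tables.

**A synthetic-cohort generator** with seroconversion test windows,
irregular visit schedules, linear or IOU trajectories, measurement error,
CD4-threshold-driven (informative) cART initiation and
proportional-hazards outcomes — plus the ground truth for every patient,
kept strictly out of the estimation path.

## Worked example

```python
from cd4slope import (SimulationConfig, simulate_cohort, apply_eligibility,
                      slopes_blup, summarize_slopes)
from cd4slope.slope_estimators import slopes_two_point, slopes_ols

cohort, truth = simulate_cohort(SimulationConfig(n_patients=1000, seed=6))
eligible, report = apply_eligibility(cohort)
print(report.n_eligible, report.exclusions)
for frame in (slopes_two_point(eligible), slopes_ols(eligible),
              slopes_blup(eligible)):
    s = summarize_slopes(frame, threshold=100)
    print(f"{s.method:>9}: median {s.median:6.1f} "
          f"IQR ({s.iqr[0]:6.1f}, {s.iqr[1]:6.1f})  rapid {100*s.prop_rapid:4.1f}%")
```

```
708 {'fewer_than_two_cd4': 135, 'missing_cd4_window': 4, 'missing_vl_window': 43, 'missing_both': 0, 'interval_below_3mo': 26}
two_point: median -180.7 IQR (-281.1, -106.0)  rapid 77.7%
      ols: median  -81.8 IQR (-131.3,  -52.2)  rapid 38.0%
     blup: median  -64.9 IQR ( -67.5,  -59.2)  rapid  0.0%
```

The same patients, three very different answers: the less information an
estimator borrows, the more "rapid decliners" it appears to find — the
two-point rule flags 78% of patients, least squares 38%, and the
shrinkage (BLUP) estimate none.  This ordering, and the null result
that the adjusted hazard ratio per +10 cells/µl/yr hovers at 1.0 with no
c-index gain when the outcome hazard ignores the slope, are the package's
central reproductions.

The command line mirrors the library:

```bash
cd4slope simulate --out cohort/ --seed 1 --n 1000
cd4slope filter --patients cohort/patients.csv --measurements cohort/measurements.csv --out eligible/
cd4slope slopes --patients cohort/patients.csv --measurements cohort/measurements.csv --method blup --out slopes/
cd4slope fit --patients cohort/patients.csv --measurements cohort/measurements.csv --model iou --out fit.json
cd4slope cox --patients cohort/patients.csv --measurements cohort/measurements.csv --out outcome/
cd4slope run-all --seed 1 --n 1000 --out full/
```

Input formats are two CSVs: `patients.csv` (patient_id, sex,
age_at_baseline, transmission_group, prior_aids, last_negative_date,
first_positive_date, seroconversion_date, cart_date, log10_vl_at_cart,
aids_date, death_date, last_visit_date; ISO dates, empty = absent) and
`measurements.csv` (patient_id, date, cd4, log10_vl).  The `simulate`
subcommand accepts a flat YAML config whose keys mirror
`SimulationConfig`; unknown keys are errors.

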