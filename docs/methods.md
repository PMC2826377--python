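# Methods

## The scientific question and the pipeline's shape

The pipeline asks whether the pre-treatment CD4 slope is prognostic for
AIDS or death after cART initiation, over and above the established
baseline predictors (CD4 category, log10 viral load, age, prior AIDS,
injection-drug-use transmission).  It is a prognostic, not a causal,
analysis: covariates are frozen at the analysis baseline and no
treatment-strategy comparison is attempted.

Stages: cohort ingestion and eligibility → per-patient slope estimation
(three estimators plus a joint-model variant) → longitudinal model
fitting and comparison (linear mixed model vs integrated
Ornstein–Uhlenbeck) → stratified Cox outcome models with discrimination.
Two eras are supported: the cART era (baseline = treatment initiation)
and a pre-treatment era (baseline = the last CD4 count in a calendar
baseline year, follow-up administratively censored at the end of 1995).

## Cohort rules

*Seroconversion* is dated at the midpoint of the last-negative /
first-positive test window; windows over 3 years are rejected.  Times for
all longitudinal modelling are years since this estimated date
(365.25 days/year); dates are handled at day resolution.

*Eligibility (cART era)*: a CD4 count and a viral load within 91 days
before initiation (inclusive), plus an earlier CD4 at least 91 days
before the windowed one.  "3 months" is encoded as 91 days to match the
91-day window; both are configurable.  When several values fall in the
window the one closest to initiation is the baseline (ties to the later
date; since all candidates precede initiation this is simply the latest).
Exclusion reasons are assigned in a fixed order — fewer than two CD4
counts, then the missing-window categories, then the too-short interval —
so each excluded patient is counted exactly once.

*Endpoints*: time from baseline to the first new AIDS event or death
(or death alone), censored at the last clinic visit.  Event times at or
before baseline are invalid records.  In the pre-treatment era the
`cart_date` column records the start of *any* antiretroviral therapy;
the sensitivity variant drops patients treated by the baseline year and
censors at therapy start otherwise.

## Longitudinal models

All three models are Gaussian and fitted by maximum likelihood (REML
optional for the mixed model) with the fixed effects `(β0, β1)` profiled
out by generalised least squares.  Variance parameters are optimised on
log (SDs, α, σ²) and atanh (correlation) scales by L-BFGS-B with
central-difference gradients and three deterministic starts; a
Nelder-Mead rescue runs if every gradient start fails.  Per-patient
covariance matrices are built in batches grouped by visit count; a
relative ridge of 1e-8 × mean diagonal guards against spurious likelihood
divergences when the residual SD collapses against a rank-deficient
random-effects covariance (a real failure mode found during development).

**Linear mixed model.** Random intercept and slope, correlated by
default (the independence structure is a constrained refit, also used as
a fallback when the fitted correlation hits ±1).  BLUPs are conditional
means `G Zᵢᵀ Vᵢ⁻¹ (yᵢ − Xᵢβ̂)`; a patient with a single measurement at
t = 0 receives a slope BLUP exactly equal to β1 under independence —
with correlated effects the intercept information leaks into the slope,
which is the behaviour verified in tests.

**IOU model.** Random intercept, fixed population slope, integrated OU
process with stationary-start kernel

σ²/(2α³) · (2α·min(s,t) + e^(−αs) + e^(−αt) − 1 − e^(−α|s−t|)),

plus measurement error.  The kernel is computed with `expm1` so the
α → 0 limit (τ²·s·t with σ² = 2ατ², the random-slope covariance) is
numerically benign.  α → ∞ with σ²/α² = κ fixed gives the Brownian
kernel κ·min(s,t).  The confidence interval for α is by profile
likelihood, because the Brownian plateau routinely makes the upper limit
unbounded — a Wald interval cannot express that.  Along the profile the
nuisance optimisation is started from the MLE and from starts matched to
the two invariants (κ = σ²/α² and τ² = σ²/2α), without which distant α
values under-optimise and fake profile roots appear.

**Identifiability of α.**  α is only identified when the visit spacing Δ
resolves the velocity correlation time 1/α (non-negligible e^(−αΔ)) and
the velocity increment τΔ exceeds the measurement error.  Under
realistic twice-yearly schedules and large α the likelihood is flat from
α ≈ 30 upward — exactly why the upper confidence limit is unbounded on
cohort-like data.  The parameter-recovery experiments therefore use
dense, low-noise schedules (visits every 0.05 years, error SD 1 cell/µl
for α = 20; every 0.15 years, error SD 15 for the coverage study at
α = 5); these are designed experiments, not cohort emulations.

**Joint model.** The mixed model is coupled to a proportional-hazards
model for time from seroconversion to cART initiation: baseline hazard
piecewise-constant on four pieces cut at quartiles of observed initiation
times, multiplied by exp(γ0·b0 + γ1·b1 [+ δ·calendar]).  The shared
random effects are integrated out by pseudo-adaptive Gauss–Hermite
quadrature (9 points per dimension) centred on each patient's Gaussian
posterior given the longitudinal data alone, which is available in closed
form; the survival factor is the only part quadratured.  Internally the
fixed effects and associations are rescaled by the estimated
random-effect SDs so the optimiser sees O(1) parameters (this cut fitting
time about six-fold).  Quadrature adequacy is verified by a doubling
check (refit at 18 points if the log-likelihood shifts by more than 0.1).
Corrected BLUPs are posterior means of (b0, b1) given both the
measurements and the initiation time.

**Model comparison** is by AIC on square-root-transformed counts: the
LMM and IOU models are non-nested in general and α sits on a boundary
under the null, making likelihood-ratio calibration dubious.  Slopes are
*reported* on the raw scale (sqrt-scale slopes are back-mapped by the
delta method at the patient's mean fitted value), matching the dual
convention of interpretable raw-scale slopes and better-behaved
sqrt-scale model fits.  One caveat found empirically: on cohorts
generated with raw-scale additive error, the sqrt transform induces
curvature that the IOU's serial correlation absorbs, so AIC can prefer
the IOU even under a linear generative trajectory; the comparison's
power/null tests therefore generate data that are exactly Gaussian on
the fitted scale.

## Survival analysis

Cox models use Efron tie-handling (lifelines) and Wald intervals.  The
slope enters per +10 cells/µl/yr so its hazard ratio is directly the
reported quantity; "higher slope" means less steep decline.  Strata are
the baseline CD4 category (<100, 100–<200, 200–<350, ≥350 cells/µl)
crossed with injection-drug-use transmission.  Five-year risk scores are
1 − exp(−H0_s(5)·exp(lp)) with a per-stratum Breslow baseline; the
c index is Harrell's, over pairs (i, j) with t_i < t_j, t_i ≤ horizon
and subject i an event, score ties counting one half.  For the
discrimination of the slope alone the score is the sign-flipped slope.
Event-rate intervals use the normal approximation to the Poisson count,
100·(n ± 1.96√n)/person-years floored at zero — the convention that
exactly reproduces the printed interval for 255 events in 10,296
person-years.  Slope-quartile cut points are the empirical 25/50/75
percentiles with values at a cut going to the lower quartile.  Degenerate
fits (constant covariate, separation) are flagged, not raised.

## The synthetic cohort generator

Per patient: a test window of width uniform on (0, 3] years with the true
infection date uniform inside it; monitoring starts at diagnosis (the
first positive test), so measurement times are non-negative relative to
the midpoint estimate; visit gaps exponential with mean 0.5 years (a
fixed-interval alternative exists for designed experiments); CD4 from the
linear (β0 = 600, β1 = −60, SD(b0) = 150, SD(b1) = 25 cells/µl/yr) or
IOU (α = 10, τ = 60) trajectory plus N(0, 100²) assay error, observed
values floored at zero (the latent path is never floored); cART initiated
at the first visit where the trigger value is below 350 cells/µl and a
Bernoulli(0.75) fires; post-initiation event times exponential with rate
0.025/year × exp(linear predictor) on covariates frozen at initiation
(coefficients per CD4/100, log10 VL, age/10, prior AIDS, slope/10;
centred at typical values; the slope coefficient defaults to zero — the
null the headline analysis reproduces), administratively censored five
years after baseline.  Randomness is one stream per patient keyed by
(seed, index), so cohorts extend without perturbing earlier patients.

The *trigger* of initiation matters more than it looks.  Triggering on
the *observed* (noisy) CD4 is a missing-at-random mechanism: the mixed
model conditions on exactly the values that drove truncation and its ML
estimates stay consistent (verified: bias ≈ 2 cells/µl/yr), leaving the
joint model nothing to correct — it slightly overcorrects instead.
Triggering on the *latent* CD4 is missing-not-at-random: the naive mixed
model then understates the decline by ~10 cells/µl/yr at the default
noise level, and the joint model recovers most of it.  Both triggers are
available (`cart_trigger`), defaulting to "observed"; the joint model's
bias-reduction property is demonstrated under "latent".

What the generator does *not* emulate: real visit-scheduling behaviour
(sicker patients attend more often), calendar trends in treatment
guidelines, regimen assignment, viral-load trajectories (a single value
at initiation, optionally correlated with the slope), or competing risks.
Passing tests therefore show the estimators and models behave correctly
under the stated statistical structure — not that real cohort data obey
that structure.

## Problem sizes used in the test suite

Simulation-backed checks run at deliberately chosen sizes: mixed-model
recovery at n = 1,000 (slope within ±3 cells/µl/yr of −60 without
treatment truncation); IOU recovery at n = 300 dense-schedule patients
(α = 20 within 30%); profile-interval coverage at 200 cohorts of n = 150
(coverage within [0.90, 0.99]); the headline pattern at three n = 1,200
large-α cohorts (adjusted slope-HR interval covering 1 in at least two,
median c-gain ≤ 0.01) plus one effect cohort (interval excluding 1); the
pre-treatment-era slope effect at n = 3,000, sized by a power analysis
accounting for shrinkage attenuation (corr(BLUP, true slope) ≈ 0.6);
joint-model checks at n = 150–200 with five replicates.  Replicate
counts for stochastic properties were fixed before running and are
evaluated by majority rules stated in each test.

## Known limitations

- The IOU fit's multi-start quasi-Newton can, on flat likelihoods, stop
  anywhere on the large-α plateau; the *profile interval*, not the point
  estimate, is the meaningful summary there.
- The joint model's piecewise-constant baseline (4 pieces) is coarse;
  it is a missing-data device, not a model of initiation policy.
- Because initiation happens at visits, time to initiation and
  per-patient information content are coupled, which makes the
  association direction weakly identified when the true association is
  zero: the likelihood is nearly flat along a (γ, β1) ridge and the
  fitted association wanders at a few hundred patients, tightening
  roughly as 1/√n.  The decoupled-case agreement between joint and
  marginal BLUPs is therefore verified at n = 2,000.
- Profile-likelihood intervals are asymptotic; at n = 150 the coverage
  study allows for mild anticonservatism (the verified band is
  0.90–0.99 rather than a two-sided band around 0.95).
- The two-sided acceptance of "observed" vs "latent" initiation triggers
  means the generator's default does not exercise the joint model's
  raison d'être; switch triggers for that.
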