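# Methods

## Scope and intent

`riskpath` implements annual-cycle risk-factor *time-path* equations for
type 2 diabetes: seven continuous risk factors, four absorbing binary
conditions, and a two-part eGFR model, plus the estimators needed to refit
each family from annualised panel data and the machinery to validate a
coefficient set against a panel. It deliberately contains **no mortality,
event-cost or utility model**: simulated trajectories are conditional on
survival and are designed to feed a downstream outcomes simulation. Using
the mean paths directly as population projections over long horizons would
ignore survivorship and should be avoided.

## The annual cycle

Each simulated year, for every patient:

1. **Events.** For each at-risk condition (AF, albuminuria, PVD), the
   Weibull proportional-hazards equation on the diabetes-duration scale
   gives `H(t) = exp(x'β) t^γ`, and the one-year conditional probability
   `p = 1 − exp(H(t) − H(t+1))`. In stochastic mode a uniform draw flips the
   absorbing flag; in expected mode probabilities are recorded without
   flipping (for calibration and Π(1−p) accumulation). Covariates labelled
   "last year" are read from the start-of-cycle state.
2. **eGFR.** The below-60 crossing uses the same Weibull machinery; the
   continuous value then comes from the regime-matched Tobit equation —
   stochastic mode draws from a truncated normal around the latent mean with
   the published forecast SD, deterministic mode uses the closed-form
   truncated-normal mean. The value is always on the correct side of 60 for
   the regime in force; once below 60, the patient stays in that regime.
3. **Continuous factors.** The seven dynamic equations advance one year;
   `ln(duration)` is evaluated at the predicted year.

All three sub-steps read the start-of-cycle (lagged) state, so their
internal order cannot affect results; the implementation runs events → eGFR
→ continuous. Duration then increments by one.

Time `t` is continuous diabetes duration, not an integer cycle index, so
`H(0) = 0` handles newly diagnosed patients; duration is floored at 0.5
years before logging (inert for realistic cohorts with ~16-year durations).

## Key conventions

**First-value anchor (`y_0`).** At simulation start, year-1 predictions use
the pre-randomisation baseline for both the lag and the anchor. From year 2
onward the anchor either stays at baseline (`y_first_source="baseline"`, the
default for extrapolating from pre-randomisation data) or switches to the
simulated year-1 value (`"first_simulated"`, used when emulating trial
panels where `y_0` is the first post-randomisation measurement).

**Interventions.** An intervention is a one-off additive shift applied to
the year-1 simulated values *and* to the first-recorded anchor. This mirrors
how modellers impose a first-year treatment effect and let the equations
extrapolate: the arm difference then follows
`D_1 = Δ, D_k = φ1 D_{k−1} + φ2 Δ`, i.e. a transient geometric channel plus
a persistent anchor channel with floor `φ2 Δ/(1−φ1)`. Persistent-effect
(every-year) interventions are out of scope.

**Random numbers.** Every patient owns one substream per equation, keyed by
`SeedSequence([seed, crc32(patient_id), stream_index])` with an append-only
stream registry. Consequences: runs are byte-reproducible from the seed;
permuting the cohort permutes output rows only; two scenario arms run with
the same seed share common random numbers; and adding a new equation never
perturbs existing draws. The patient random intercept `μ_i` is drawn once
per patient and reused every year; `ε_it` is drawn fresh annually.

**Clamping.** Continuous predictions are not clamped to physiological
ranges by default; an optional clamp (same ranges as the preprocessing
filter) can be switched on. The open-ended above-60 eGFR regime has a
configurable physiological cap (default 200 ml/min/1.73m²).

## Bundled coefficients

The default bundle transcribes the published pooled-trial tables at their
printed 3-decimal precision (full-precision values were never published;
small reproduction differences at the 3rd decimal are inherent). The
residual and random-effect SDs of the dynamic equations were not published;
they default to 0 — making default simulations deterministic in the
continuous factors — and are populated when equations are refit. The Tobit
"sigma" is the published forecast standard error, treated here as the total
draw SD (whether it conflates residual and random-effect variance is not
stated in the source). Reference ethnicity is "other" (non-white, non-black,
non-Asian) throughout; eGFR units are ml/min/1.73m², HbA1c is in %, and the
Table-1 units are assumed for the survival-equation covariates.

## Estimation

* **Dynamic equations** — Gaussian random-intercept ML (statsmodels
  MixedLM) with the lagged and first-recorded values as regressors, exactly
  the quasi-likelihood used in practice for these equations. This estimator
  has the classic dynamic-panel *initial-conditions* property: because the
  random intercept also feeds the observed first post-randomisation value
  and the lags, the ML converges to the parameters of the conditional law —
  the lag coefficient, demographics and both variance components are
  recovered, while the first-value coefficient and constant absorb the
  projection of `μ_i` on `y_0` (`φ2 → φ2 + σ_μ²/Var(y_1|x)`). For
  *prediction*, the composite is the right object; for recovery studies the
  shift is verified against a projection oracle in the test suite. No
  instrumental-variable correction is attempted. A random-intercept variance
  estimated below 1% of the residual variance is collapsed to the boundary
  and the pooled OLS fit reported (numerical tie-break). R² is reported as
  the squared correlation of fixed-effect predictions with observations.
* **Tobit equations** — pooled censored-normal MLE (`β`, `log σ` via BFGS,
  SEs from the numeric Hessian): the below-60 model right-censors values at
  60 with limits (0, 60); the above-60 model left-censors at 60. A pooled
  (rather than random-effects) Tobit matches the single published forecast
  SD. Data at both limits contribute probability mass, interior data
  density; fully censored samples raise an identifiability error.
* **Parametric PH** — left-truncated counting-process MLE over per-year
  covariate intervals, `Σ [d·ln h(t1) + H(t0) − H(t1)]`, for Weibull,
  exponential and Gompertz hazards; AIC compares the three. Left truncation
  at trial entry is mandatory because cohorts enter ~16 years
  post-diagnosis. Standard errors are cluster-robust (sandwich over
  per-patient scores), matching the robust-SE convention for these tables.
* **Stepwise** — backwards elimination on Wald p-values at α = 0.05;
  among ties the later-declared covariate is removed; shape parameters and
  the constant are never candidates. May return a constant-only model.
* **Cox–Snell residuals** — `Ĥ(exit|x) − Ĥ(entry|x)` per patient; under a
  correct model the event residuals behave as unit-exponential (Nelson–Aalen
  slope ≈ 1). Schoenfeld-residual diagnostics are not implemented.

## Synthetic data

`generate_cohort` draws baselines that *emulate* a contemporary pooled-trial
population: age ~ N(64, 8²), diabetes duration lognormal with mean 16 y,
30% female, ethnicity mix 75/6/12/7% (white/black/Asian/other), 11% baseline
smokers, and clinically plausible risk-factor means/SDs (e.g. HbA1c
7.5 ± 1.2%, SBP 135 ± 16 mmHg, eGFR 75 ± 18) with a mild correlation
structure. These are generator defaults chosen for plausibility — **not**
estimates from any trial's (non-public) baseline table — and every number is
overridable. Infeasible correlation matrices are repaired to the nearest
positive-definite matrix with a warning.

`generate_panel` simulates forward with the package's own stochastic
engines (anchor = first simulated value, as in trial panels), records exact
event onset times by inverting the conditional Weibull CDF within the onset
year, then applies non-informative annual dropout, measurement noise and
per-factor missingness. What passing recovery/validation tests on such
panels shows is that the estimators and validators are correct *for the
model class*; they cannot certify the equations against real-world
deviations (informative dropout, measurement artefacts, treatment switching,
survivorship), which the generator does not emulate.

Two deliberate mismatches between simulator and estimator model classes are
handled explicitly:

* The simulator's eGFR values are regime-conditional *truncated* draws,
  which is the right projection behaviour but not the censored-normal DGP
  the Tobit likelihood assumes; Tobit recovery studies therefore use a
  dedicated latent-normal AR(1) panel generator
  (`riskpath._tobitpanel.generate_tobit_panel`).
* With stochastic eGFR draws, the below-60 crossing hazard is convex in the
  lagged eGFR, so path-averaged stochastic incidence systematically exceeds
  the deterministic-path product Π(1−p) (a Jensen gap of ~10% relative for
  the crossing). The expected-vs-stochastic consistency experiment therefore
  holds the value draw at the truncated mean
  (`SimulationConfig(egfr_value_mode="deterministic")`) to isolate the
  Monte-Carlo binarisation, which is unbiased.

`preprocess_panel` annualises raw visit data with the trial conventions:
drop post-randomisation measurements under 6 months (initial treatment
effect), filter values outside per-variable plausibility ranges (the bundled
ranges are documented placeholders — the original range list is not
reproduced — and should be overridden), average within patient-year windows,
and exclude patients without baseline, without follow-up, who withdrew at
randomisation, or with missing ethnicity; every exclusion is counted. The
operation is idempotent.

## Validation

Observed-vs-predicted comparisons pool patients by integer diabetes
duration (period-life-table style), so six years of follow-up per patient
trace a multi-decade path. Observed bin means carry normal-approximation
95% CIs (the CI construction of the source figures is not stated; pointwise
normal intervals are used); agreement means the prediction lies inside the
CI. One-step-ahead predictions on observed lags are the default for internal
validation; fully re-fed simulation is used for extrapolation-style checks.
Quintile calibration stratifies on the first observed value with ties
assigned to the lower quintile.

Cumulative incidence uses the delayed-entry Kaplan–Meier estimator
(cumulative incidence = 1 − KM survivor, Greenwood CIs) against
model-implied incidence from pooled annual hazards chained per duration bin.
Both curves are conditioned on the first well-populated bin that has seen an
observed event — before that the Greenwood interval is a point mass at zero
and the comparison is vacuous. Bins with fewer at-risk patient-years than a
threshold are dropped (reported in the output).

## Problem sizes and numerical choices

The test suite runs the consistency experiment at 10⁵ patients × 8 years,
dynamic recovery at 5,000 patients × 6 years (residual SD 0.5, random-effect
SD 0.3 for HbA1c), Tobit recovery at 8,000 patients, PH recovery and AIC
selection at 20,000 subjects × 100 replicates (40% delayed entry, ~70%
censoring, shape 1.21), validation self-consistency at 10,000 patients, and
stepwise operating characteristics over 200 replicates; the acceptance
script uses the same designs at moderately smaller replicate counts. These
sizes give Monte-Carlo SEs comfortably inside the 3-SE tolerances used
throughout.

Optimisers: BFGS with numeric gradients for Tobit and PH likelihoods
(starting values from OLS / the event-rate constant); L-BFGS ML for the
mixed model. Tail-safe truncated-normal formulas switch between CDF- and
survival-function branches; a truncation window carrying < 1e-12 probability
mass falls back to the clamped latent mean. Gompertz hazards use an
`expm1`-based cumulative hazard with a series branch near rate 0.

## Known limitations

* No mortality or competing risks between the four conditions; no treatment
  effects inside the equations (interventions are one-off shifts).
* Printed 3-decimal coefficients limit reproduction precision.
* The dynamic-equation error-component SDs are unpublished; default-bundle
  simulations are deterministic in the continuous factors unless the user
  supplies or refits them.
* The RE dynamic estimator's first-value coefficient is a conditional-law
  composite, not the structural `φ2` (see Estimation above).
* White-blood-cell count and smoking trajectories, trial-specific and
  treatment-arm coefficient sets, and automatic unit conversion are out of
  scope.
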