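# Methods

This note documents the model implemented in `strokecea`: its structure,
parameters, numerical conventions, the synthetic-data layer, and the
choices made where the design was genuinely open.

## Model structure

**Acute phase (decision tree).** A cohort of 80-year-old stroke patients
receives one of eight strategies (standard of care alone or with any
combination of metoclopramide, ceftriaxone, paracetamol). The strategy
determines the probability vector over mRS 0–6 at 90 days; everything
else in the acute phase is conditional on the attained state. Acute cost
per state = location days x per-day costs (hospital 683, rehabilitation
379, nursing home 308 euro; days at home are costed at the state's
weekly long-term care rate / 7) + procedure costs (thrombolysis 1,130,
thrombectomy 11,797, weighted by per-state use; carotid endarterectomy
5,426 at 6%) + per-patient follow-up costs (visits 250, diagnostics 586,
allied health 257). Follow-up and endarterectomy costs apply to
survivors only; the death state keeps its (truncated-stay) location and
procedure costs. Per-course drug cost is the sum of component prices
(Met 1.08, Par 1.60, Cef 74.72 euro) plus one intravenous infusion (180
euro) for ceftriaxone-containing strategies — ceftriaxone is the only
IV-only component; a config switch (`infusion_rule`) extends the charge
to all active arms or removes it. Acute QALYs are 90/365.25 years at the
state utility (mRS 0–6: 0.94/0.85/0.78/0.59/0.30/0.14/0), zero for
decedents; no within-phase utility trajectory is modelled.

**Long-term phase (weekly Markov cohort).** Survivors enter at age
80 + 90/365.25 and are followed in 1-week cycles until 20 years or age
100, whichever comes first (1,030 cycles). Weekly events per alive
state:

* *Other-cause death*: baseline weekly rate log-linear in age between
  0.001 (age 80) and 0.008 (age 99), clamped above 99 — a Gompertz-type
  schedule consistent with national life tables (annual ~5% at 80, ~34%
  at 99) — multiplied by mRS-specific hazard ratios 1.20 (mRS 0) and
  1.42/1.87/2.17/3.1/6.91 (mRS 1–5).
* *Recurrent stroke*: Weibull cumulative hazard H(t) = (t/scale)^shape
  with log-shape −0.57 and log-scale 5.49; shape < 1 gives the observed
  declining recurrence risk. The hazard is multiplied by mRS-group
  ratios (1 / 1.18 / 1.36 for mRS 0 / 1–2 / 3+) and renormalized so the
  SoC survivor mix has average ratio exactly 1, preventing the
  adjustment from inflating the calibrated baseline risk. A recurrence
  redistributes the patient over same-or-worse states using the SoC
  90-day vector truncated at the current state (death included — a
  recurrent stroke can kill).

Mortality and recurrence compete as exponential rates within a cycle:
the total event probability is 1 − exp(−(m+r)) split proportionally,
which removes order-of-application artefacts at weekly resolution. Costs
(weekly long-term care by state: 127/127/183/412/925/1,208 euro for mRS
0–5, zero when dead, plus an age-linear indirect medical cost 0 → 704
euro/week from 80 to 99, switchable off) and QALYs (state utility /
52.18) accrue on start-of-cycle occupancy and are discounted
continuously from the stroke at 3%/year (costs) and 1.5%/year (QALYs);
a common 3.5% scenario is provided. No half-cycle correction is applied
— the weekly cycle itself keeps the discretization error far below the
parameter uncertainty.

**Decision metrics.** NMB = QALY x lambda − cost; ties broken toward the
cheaper strategy (a deterministic reporting convention for a
risk-neutral rule). The efficiency frontier removes strictly dominated
strategies, then extendedly dominated ones (ICERs must increase with
cost), and reports segment ICERs. Proportional shortfall =
(general-population QALE − patient QALE)/general-population QALE, with
the matched-population QALE (6.61 undiscounted QALYs) entering as a
config input because its derivation is external to the model; the Dutch
band mapping (0.10–0.40 / 0.41–0.70 / 0.71–1.00 → 20/50/80 thousand
euro/QALY) picks the operative threshold.

## Calibration of the recurrence time scale

The printed Weibull parameters come without a time unit. The registry
the curve was calibrated to reports cumulative recurrence risks of
roughly 4% at 1 year and ~16% at 10 years for 70–79-year-old stroke
patients. With the scale interpreted in **years** (exp(5.49) ≈ 242 y),
H(1 y) = 0.045 and H(10 y) = 0.165 — an almost exact match — whereas
weeks would imply a 34% first-year recurrence risk, which is clinically
implausible and collapses survival. The package therefore defaults to
`weibull_time_unit: years`, with `weeks`, `months` and `days` available
as config switches.

## Probabilistic sensitivity analysis

Each of the 10,000 draws samples all uncertain parameters jointly:

| group | family | hyperparameters |
|---|---|---|
| per-arm mRS vectors | Dirichlet | concentration = renormalized point estimate x effective sample size 1,493/8 ≈ 187 |
| Weibull log-shape / log-scale | normal | SE 0.1 (stand-in) |
| recurrence & mortality HRs | lognormal | moment-matched, CV 0.1 (stand-in); the reference HR (mRS 0 recurrence = 1) stays fixed |
| utilities (mRS 0–5) | beta | moment-matched, SE 0.02 (stand-in) |
| lengths of stay, unit costs, LTC costs, procedure proportions | gamma | moment-matched, CV 0.2 (stand-in); proportions clipped to [0, 1] |
| carotid proportion | beta | SE 0.02 |
| drug costs, baseline mortality, indirect costs | constant | — |

The source analysis's distribution hyperparameters are not public; the
values marked *stand-in* are deliberate, conservative defaults exposed in
the config (`uncertainty:` block) and should be treated as scenario
knobs. Dirichlet concentrations use the unrounded renormalized
probability vector so that the sampling mean reproduces the point
estimate exactly. Samplers are driven by one `numpy` generator in a
fixed order, so a seed reproduces a draw matrix bit for bit. The
engine is vectorized over draws — one 10,000-draw PSA of all eight
strategies runs in well under a minute on one CPU.

CEAC values are per-draw argmax frequencies of NMB (exact ties to the
cheaper strategy); the CEAF reports the probability attached to the
strategy with the highest *mean* NMB, which is the decision-relevant
curve and need not be the modal winner.

## Value of information

EVPI is the two-term contrast `mean(max NMB) − max(mean NMB)` on the
per-draw NMB matrix. EVPPI uses the regression estimator: each
strategy's NMB is regressed on the draws of one parameter group and the
contrast is applied to fitted values. EVSI simulates, per retained PSA
draw, one trial dataset (per-arm multinomial mRS counts, even allocation
with largest-remainder rounding) and regresses NMB on the per-arm
conjugate Dirichlet posterior means — sufficient statistics for the
multinomial likelihood, so no information is lost in the summary.

Two regressors are supported (config choice): a gradient-boosted
additive tree ensemble (default) and a smooth additive spline model with
ridge shrinkage. The tree ensemble uses validation-based early stopping;
without it, fitted values chase Monte-Carlo noise, and because the
estimand takes a maximum over fitted values this inflates EVPPI/EVSI.
The calibration was checked against internally computable references:
for this model the conditional mean of each strategy's NMB given an
arm's mRS vector (and given the posterior-mean summaries) is exactly
linear, so ordinary least squares provides a near-unbiased benchmark;
the early-stopped ensemble matches it, drives pure-noise groups to ~0,
and reproduces the two-term EVPI within 1% when given a saturated
feature set. The regression route is also verified against exhaustive
enumeration on a two-strategy conjugate toy model.

EVSI(n) at n ∈ {160, 320, 800, 4,000} is interpolated with the
asymptotic-regression curve a(1 − exp(−c·n)), constrained through the
origin with asymptote ≥ the largest observed value. Population EVSI
multiplies the per-person value by the monthly incidence of eligible
patients (41,300 x 0.75 x 0.50 / 12 ≈ 1,291) accrued from trial end
(enrollment at 80/month + 3 months follow-up + 6 months reporting) to
the decision horizon, each monthly cohort discounted at 3%/year with
monthly compounding. ENBS subtracts trial costs (4.6 million euros fixed
+ 500 euros/patient) and is maximized over n on a unit grid.

## Synthetic trial data

`generate_trial` emulates the patient-level table the trial-informed
parameters are estimated from: mRS from the arm's outcome vector;
utility as a beta variable centred on the state utility (SD 0.15,
zero for decedents); the four location stays as a normalized gamma
composition filling the state's total observed stay (≤ 90 days), so
per-location means reproduce the configured lengths of stay exactly;
procedure flags as Bernoulli draws. Missingness is imposed completely at
random at the observed completeness rates (mRS 1.4%, utility 25.5%,
procedures 13.5%, institutional stay 12.1%); a missing-at-random variant
(`mar_mrs`, heavier missingness for mRS ≥ 4) is available. The generator
does **not** emulate site effects, within-patient correlation between
utility and stay beyond the shared mRS state, measurement error in mRS,
or informative (outcome-dependent) missingness — parameter-recovery
results therefore demonstrate estimator consistency under the assumed
mechanism, not robustness to real-world missingness.

Imputation is a single-pass chained scheme (the pipeline consumes point
estimates; sampling multiplicity is represented in the PSA instead):
multinomial logistic regression on arm and mean-filled continuous fields
for mRS; logistic regression on arm and mRS for procedure flags;
predictive-mean matching within mRS stratum (5 donors) for utility and
days, with durations rescaled into the 90-day window. Imputed values
therefore never leave the observed support.

## Numerical conventions and degenerate inputs

* Printed mRS vectors may sum to 0.99–1.01; they are renormalized by
  their sum (preserving ratios), and a deviation beyond 0.02 is a
  validation error. The same tolerance logic rescales the one state
  whose printed lengths of stay overshoot 90 days by 0.1.
* A year is 365.25 days; a model week is 1/52.18 years; the acute phase
  is 90/365.25 years.
* Occupancy is checked to stay on the simplex within 1e−10 every cycle;
  transition-matrix rows must sum to 1 within 1e−10.
* Zero-mean gamma parameters are degenerate constants at 0; beta
  moment-matching falls back to a constant when the mean or variance is
  infeasible; zero mortality anchors switch the age interpolation from
  log-linear to linear so a mortality-free scenario is representable.
* Per-draw NMB ties are broken by subtracting 1e−9 x cost, which is
  orders of magnitude below one euro cent at the model's scale.

## Problem sizes

The default analyses use 10,000 PSA draws. The test suite runs its
uncertainty and VOI unit checks on 1,500 draws, the EVSI estimates on
2,000 simulated datasets per sample size, the microsimulation oracle
with 10,000 walkers, and parameter recovery with 50,000 patients per
arm; these sizes put Monte-Carlo error well inside the asserted
tolerances while keeping the full suite in a few minutes.

## Known limitations

* The uncertainty hyperparameters marked as stand-ins above shift the
  absolute EVPI/EVPPI/EVSI scale; conclusions about their ordering and
  about which group dominates are insensitive in our runs, but absolute
  euro values should be read with that caveat.
* The printed baseline mortality anchors carry one significant figure.
  Survival-scale quantities (life expectancy, undiscounted QALE,
  absolute cost levels, and through the NMB spread also the VOI scale)
  inherit that coarseness; incremental comparisons between strategies
  are far less sensitive because the same schedule applies to every arm.
* Long-term care costs are held constant per state over the horizon and
  utilities are time-invariant; recurrent strokes incur no acute-care
  cost by default (configurable via `recurrence.acute_cost_per_event`).
* The published multiple-imputation procedure is replaced by a
  single-pass chained imputation; uncertainty from missing data is not
  propagated beyond the PSA distributions.
* ENBS magnitudes depend on the population-accrual convention described
  above; alternative conventions (e.g. cohort-level rather than monthly
  discounting) rescale ENBS without changing the location of its
  optimum appreciably.
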