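# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort simulation over five health
states — PD, PD with chronic complications, HD, HD with chronic
complications, and death — with a one-year cycle.  Chronic complications
(cardiovascular disease, stroke, CKD-related mineral and bone disorders)
are irreversible: there is no transition from a chronic state back to the
complication-free state of the same modality.  Acute complications
(peritonitis, vascular-access infection) are transient within-cycle
events: they are priced as an expected per-cycle cost add-on
(probability × event cost) but cause no state change and no utility
decrement, because the utility table is resolved by chronic status only.
Death is the single absorbing state; the simulation runs until the
living cohort mass falls below 1e-8 or the cohort reaches the age cap
(100 years), whichever is first.

Transition parameters are stratified by the **initial** modality: after a
switch, a patient occupies the other modality's state (and accrues its
costs and utilities) but keeps the transition parameters of the stratum
they started in, mirroring the structure of the source parameter table
(which lists, e.g., "HD to HD with chronic complications" within the
start-with-PD column).  A single annual switch probability per stratum
applies to all living states; a chronic-state switcher lands in the other
modality's chronic state.

Within-cycle composition order is: death first (from the survival
model), then switching and chronic-complication onset split the
surviving fraction proportionally, with the remainder staying put.  If
switch + complication probabilities exceed 1 they are renormalised
proportionally and a warning is logged — this signals implausible
parameters rather than aborting, since PSA draws can occasionally stray.
No half-cycle correction is applied by default (state membership is
counted at cycle start); a `half_cycle_correction` flag averages
adjacent occupancy rows instead.  Setup cost (PD catheter / vascular
access) is charged at entry and, by default, again on each expected
modality switch (`setup_cost_on_switch` disables this).

## Parameters and distributions

All parameters live in `data/table1.yaml`: annual transition
probabilities with 95% intervals (beta), state costs in 2021 USD at
33.57 THB/USD (exponential for direct medical, gamma for non-medical and
indirect, uniform ±10% for setup), and EQ-5D utilities (beta).  Interval
→ distribution inversion uses a symmetric normal approximation,
sd = (high − low)/3.92, then method of moments; the analytic mean of
every constructed distribution equals the printed point estimate
exactly (tested to 1e-9).  Notable choices:

* **Exponential costs** are a one-parameter family; they are sampled
  with the point estimate as the mean, and the printed intervals are
  used only for one-way sensitivity bounds.
* **Gamma rows with a zero lower bound** (indirect costs) keep the same
  sd convention; a gamma cannot produce exact zeros, accepted as an
  approximation.
* **PSA draws are mutually independent**; no correlation structure is
  imposed.  A draw violating a structural invariant (chronic utility
  above the complication-free utility of the same modality) is rejected
  and redrawn with a logged count, so every accepted draw is a valid
  parameter set.
* Age at initiation is fixed per scenario in deterministic runs and in
  the default PSA.

Key analysis settings (defaults): discount rate 0.03/year for both costs
and outcomes, willingness-to-pay 4,766 USD/QALY, 5,000 PSA iterations,
WTP grid 0–60,000 in steps of 100 for the CEAC, starting age 55.7 years
(the cohort's median age at initiation) for one-way and probabilistic
analyses.

## Mortality: fitting and calibration

Per-cycle death probability is the conditional one-year probability
1 − S(t+1|x)/S(t|x) of a Weibull AFT model; chronic states apply a
proportional-hazards multiplier m ≥ 1 to the conditional survival
ratio.  Two paths provide the model:

1. **Fitting** (`fit_weibull`): maximum-likelihood Weibull AFT on
   patient-level records via lifelines, exposed with convergence
   diagnostics and standard errors.
2. **Calibration** (`calibrate_mortality`): the source study's fitted
   coefficients are not published, so a minimal model — shape, scale at
   a reference age of 50, linear and quadratic age coefficients, and
   the chronic multiplier — is recovered per strategy stratum by
   least-squares against the published discounted life-expectancies at
   starting ages 20–60.  The quadratic age term is needed because a
   single AFT age slope cannot bend the age profile of discounted life
   expectancy enough; with it, the shipped fixture reproduces all ten
   life-year targets with RMS error 0.085 years.  Published life-years
   are treated as discounted at 3%, consistent with the stated
   discounting of both costs and outcomes; a flag allows undiscounted
   calibration.  The optimiser is multistart bounded least squares and
   is fully deterministic.

Age enters mortality through the AFT linear predictor as a fixed
age-at-initiation covariable; time-dependence within a trace is carried
by the Weibull shape, not by re-evaluating the coefficient as the cohort
ages.  This is a documented simplification.  The calibrated HD-stratum
chronic multiplier sits at the upper bound of its search range (10),
i.e. the life-year targets are best served by near-maximal excess
chronic-state mortality; the fit quality is unaffected, but the
multiplier itself should not be interpreted as an epidemiological
estimate.

## Estimation procedures

* **Direct medical costs** follow a six-step aggregation: map raw
  billing labels to eight cost groups; aggregate each patient's visits
  into non-overlapping 30-day observations anchored at their first
  visit (the anchoring rule is a package choice; the source describes
  only "within 30 days"); pool patients; adjust each amount to 2021 THB
  by the supplied inflation-index ratio; classify observations into the
  eight (treatment × complication) outcome groups; summarise and
  convert to USD.  Money is conserved: total USD out equals total
  inflated THB in divided by the exchange rate.
* **Non-medical and indirect costs** are unit-costed as median (IQR) per
  visit, multiplied by visit counts or hospital days.
* **EQ-5D scoring** uses a pluggable additive tariff (constant minus
  per-dimension decrements).  The official Thai value set is not
  redistributed; a three-level toy tariff (decrements 0/0.1/0.3) ships
  for testing and the synthetic generator.
* **IPWRA**: logit propensity of PD assignment on the listed
  covariables; per-treatment linear outcome models weighted by inverse
  assignment probability (propensities truncated to (0.01, 0.99) with a
  logged count); potential-outcome means as the average counterfactual
  prediction over the whole sample, overall and by chronic status.
  "Complications" in the outcome model means the chronic indicator
  only.  Standard errors are nonparametric patient-level bootstrap.
  Records with missing EQ-5D dimensions are excluded with a count.

## Synthetic cohort

The generator emulates the statistical structure of the source data at
the stated scale (default 10,252 patients, ~18% starting on PD): age and
comorbidity marginals loosely matched to a Thai dialysis population
(illustrative package constants — no baseline table is published);
treatment assignment by a logit on age and income (confounded by
construction); Weibull event times per treatment with an AFT age and
diabetes effect and administrative censoring at up to 9 years of
follow-up; an independent exponential modality-switch process whose
annual probabilities equal the model's switch parameters; gamma 30-day
billing costs per (treatment, complication) cell over a 24-month billing
horizon; and EQ-5D profiles drawn so tariff-scored utilities equal the
target cell means (0.731/0.811 without, 0.599/0.639 with chronic
complications) plus an age effect that makes naive group means biased
while IPWRA remains consistent.  Level probabilities split each
patient's target deficit equally across the five dimensions, half
through level 2 and half through level 3, so the scored mean is exact by
construction.

What passing tests show — and do not show: recovery tests demonstrate
that the estimators are consistent and correctly implemented under a
data-generating process that matches their assumptions (correct
propensity and outcome specifications, independent censoring,
gamma-distributed costs).  They do not validate those assumptions for
any real registry, where model misspecification, informative censoring
and billing irregularities are all possible.

## Numerical choices

* Trace rows must sum to 1 within 1e-10; transition-matrix rows within
  1e-12; forbidden transitions are exactly zero.
* The cohort engine was validated against a seeded individual-level
  microsimulation (multinomial propagation of 1e5 patients in 20
  batches): expected cost, LY and QALY agree within 3 Monte-Carlo
  standard errors across random parameter draws.
* Tornado analysis varies one parameter at a time to its interval
  bounds (±10% for setup costs), holding the rest at base; entries with
  an undefined ICER at a bound are flagged and excluded from the
  ranking; a base ICER outside the [low, high] pair (non-monotone
  response) is logged, not treated as an error.
* CEAC ties in net monetary benefit are split equally; the crossover
  WTP is linearly interpolated where the acceptability curves cross
  0.5, and reported as absent if they do not cross on the grid.
* Problem sizes in the shipped test-and-reproduction runs: 5,000 PSA
  iterations, 1e5-patient microsimulation batches, 10,000-patient
  synthetic cohorts — sizes at which Monte-Carlo error is small
  relative to every tolerance used.

## Known limitations

* Kidney transplantation, automated PD and hemodiafiltration are out of
  scope, as in the source analysis.
* The calibrated mortality fixture reproduces life expectancy, not the
  underlying hazard shape; absolute QALY and cost levels consequently
  deviate from the published cells by up to ~6% and ~8% respectively
  (within the ±10% reproduction band the package tests), and ICERs by
  more, since they compound both deviations.
* No memory beyond (initial stratum, current state): time since
  complication onset and number of switches are not tracked.
* The PSA mean outcomes differ from the published PSA means more than
  the deterministic cells do; the published analysis also sampled age
  (gamma), which is off by default here because its distribution
  parameters are not stated.
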