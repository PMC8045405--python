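# Methods

This note records the models as implemented, the defaults and why, and the
decisions taken where the underlying procedures admit more than one
reasonable reading.  Nothing here states a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Exposure model

Drug kinetics are deliberately minimal: a central compartment with
first-order elimination `k_e = log 2 / T_e` and an effect compartment that
relaxes toward the central concentration at rate `k_eff`, both with unit
volume, and instantaneous bolus input of the nominal dose at each
administration time (`first_dose_time + k·interval` within the cycle).  The
closed-form superposition of per-bolus responses

    Ceff(t) = Σ_k d · k_eff/(k_eff − k_e) · (e^{−k_e τ_k} − e^{−k_eff τ_k}),
    τ_k = t − t_k ≥ 0,

and its term-by-term integral are used everywhere; when
`|k_e − k_eff| < 1e−8 · k_e` the analytic confluent limit
`d · k_eff τ e^{−k_eff τ}` replaces the difference quotient for stability.
The test suite verifies the closed form against adaptive ODE integration to
1e−6 relative across half-lives 5–50 h and `k_eff` 0.05–2.5 /h.

Defaults mimic everolimus: `T_e = 30 h`; `k_eff = 0.37 /h`.  The latter is
the mean of the log-normal whose central 95% interval spans one turnover
per cycle (1/504 /h) to the absorption rate (2.5 /h) — `derive_k_eff()`
recomputes it.  An alternative reading of that elicitation would put 0.37
on the log scale (`k_eff = e^{0.37} ≈ 1.45 /h`); since 0.37 is exactly the
constructed distribution's mean, the plain-scale value is the default and
any other value can simply be passed to `PKParams`.

Exposure is normalised by a reference schedule (simulations: 7.5 mg daily;
everolimus reanalysis: 5 mg daily) so that its cycle-1 AUC is exactly 1;
this makes `log β` interpretable as `cloglog` of the reference-schedule
end-of-cycle DLT probability and is enforced to 1e−8 in the tests.

## TITE-PK posterior and decisions

With a single parameter, the posterior of `log β` is computed by
quadrature on a uniform grid spanning ±8 prior sd with 2001 nodes (1001 in
the trial simulator; the overdosing probabilities agree to ~1e−3).  The
likelihood reduces to three sufficient statistics (event count, Σ log E(T)
over events, Σ AUC_E(T)), so refitting after each cohort is cheap.  An
emcee backend cross-checks the grid; agreement within 0.01 on the bundled
dataset is part of the acceptance suite.

Classification uses the targeted-toxicity interval (0.20, 0.40) and the
feasibility bound 0.25, strict inequality (`P_overdose = bound` is not
admissible).  Among admissible regimens the one with the highest cycle-1
exposure AUC is recommended.  The literal alternative — recommending the
*lowest* admissible exposure — is available as
`escalation_rule="lowest_auc"`, but it can never escalate and contradicts
the analogous highest-admissible-dose rule of the BLRM, so the highest-AUC
rule is the default.

Administrative censoring before the cycle end is accepted in data records;
the bundled data and the simulator only censor at the cycle end.

## BLRM, MAP and robust MAP

Two-parameter logistic model on `(log α₁, log α₂)` with bivariate-normal
mixture priors.  Posteriors are per-component tensor grids (401 × 401 over
±6 component sd; 101 in the simulator) with mixture weights updated by the
component marginal likelihoods; 401 nodes keep the exceedance-probability
quantisation error below the 0.01 backend-agreement tolerance.  Weakly
informative presets: `σ = (2, 1)` centred at `logit(0.30)` at the reference
dose (simulation preset, reference 7.5 mg) and `σ = (1.25, 1)` (everolimus
preset, reference 5 mg).

The MAP prior for a new schedule fits a hierarchical BLRM to the completed
schedule's counts, doses rescaled to the new schedule's scale by the ratio
of dosing intervals (weekly→daily: ÷7) so nominal doses match cumulative
dose.  Schedule-level parameters are exchangeable around population means
(hyperprior: the WIP) with between-schedule sds `τ` given half-normal
priors.  The `τ` scales are not derivable from first principles; the
default `(0.25, 0.125)` is the conventional "substantial heterogeneity"
scale for a log-odds parameter, halved for the log-slope.  Wider choices
(e.g. scales of 1) leave the predictive nearly as diffuse as the WIP and
defeat borrowing.  The posterior-predictive draws `θ_new = μ + τ·z` are
moment-matched to a single bivariate normal; robustification mixes it with
the WIP at weight 0.8.  The hierarchical step is the package's only
sampled posterior (emcee, 32 walkers, 3000 steps, seeded); its Monte-Carlo
wobble on the everolimus overdosing probability is below ±0.01 across
seeds.

## CRM and bridging

Power model `π_j = p_j^{exp(α)}`, `α ~ N(0, 2²)`, 1-D quadrature over ±10
prior sd.  Skeletons come from the indifference-interval calibration: the
prior-MTD position carries the target, and neighbours are spaced so that
at the exponent where level `k` reads `target ∓ δ`, level `k±1` reads
`target ± δ` (δ = 0.10).  Recommendation is the dose with posterior-mean
probability closest to the target, ties to the lower dose.  The safety
rule stops when `P(π₁ > 0.30) > 0.90`, strict: the worked everolimus
example continues the trial at `P = 0.80` precisely because it is below
0.90, which fixes the inequality's direction (the opposite direction would
stop every trial at the first fit).

The bridge estimates the completed schedule's dose-toxicity curve twice —
a bounded probit MLE on standardised dose (|coefficients| ≤ 10, which
keeps separated data finite) and the weighted isotonic MLE — and blends
them per level with weight `λ/(λ+1)`, `λ` the binomial likelihood ratio
with probabilities clipped at 1e−6.  Untried levels take the probit curve,
the stepwise-carried isotonic value and weight ½.  Dose levels of the two
schedules correspond **by rank**: skeleton position j of the new schedule
inherits the estimate at dose level j of the completed schedule.  In the
simulation scenarios both grids have six levels so rank equals dose; in the
everolimus reanalysis the two weekly levels map to the two administered
daily levels.  The alternative — evaluating the probit curve at
cumulative-dose-rescaled new-schedule doses — was rejected: with only two
completed-schedule levels the saturated probit is a near step function and
the resulting skeletons are degenerate.  Model averaging uses equal prior
weights over the three shifted skeletons and quadrature marginal
likelihoods.

## Trial simulator

Cohorts of 3; starting dose the lowest level; maximum 60 patients per
schedule step for the EWOC designs, a fixed 21 for the CRM designs.  Per
patient, a DLT occurs with the scenario's true probability; its time is
drawn uniformly on (0, t*] (`dlt_time_rule="uniform"`), with a fixed
day-15 variant available.  The timing rule is a genuine degree of freedom
of the study design — the Bayesian models see event times, so it shifts
how alarmed TITE-PK is — and the uniform default is the neutral choice;
the sensitivity scan quantifies the direction (earlier events ⇒ higher
estimated overdosing probability).

Decision rules, where the procedure admits variants:

* **Stop**: if every dose in the grid fails EWOC, stop without an MTD
  (checked after every cohort, from the first).
* **Declare**: a dose is declared MTD when the model *keeps recommending
  it* — the recommendation equals the dose the current cohort was just
  treated at — and it carries ≥ 6 patients with ≥ 21 treated in the step.
  The greedy alternative (declare any recommended dose that happens to
  have ≥ 6 patients) lets one borderline refit re-admit a toxic dose and
  immediately crown it; the stability requirement removes that artefact.
* **Escalation increments**: unconstrained by default (`no_skip=False`);
  the EWOC bound itself is the guardrail.  A no-skipping restriction is
  available.
* **Sequential start**: the second schedule starts at the highest dose
  admissible under the carried-over model (pooled posterior for TITE-PK,
  robust-MAP prior for the BLRM); the bridging CRM, which carries no
  posterior, starts at the lowest dose.  `s2_start="lowest"` restores the
  conservative variant.
* **Accounting**: sequential metrics describe the second schedule's step;
  if the programme dies in the first schedule, the patients counted are
  those enrolled up to the stop.  Selection outcomes (targeted 0.20–0.40
  inclusive, overdosing > 0.40, underdosing < 0.20, none) partition the
  replicates; Monte-Carlo standard errors use `√(p(1−p)/R)`.

The acceptance suite exercises four simulator cells at 4,000 replicates
each (a no-overdose single-schedule grid, an all-toxic grid, and their
sequential counterparts); the replicate count is set so Monte-Carlo error
is small against the comparison tolerances while the whole suite stays in
a few minutes on one CPU.

## What the simulator does and does not emulate

Scenario truths are per-dose DLT probabilities; they need not be — and in
the monotonicity-violating scenario deliberately are not — consistent with
any single exposure-toxicity curve, so simulation results probe model
misspecification, not just estimation.  Not emulated: staggered entry and
partial follow-up within a cycle (all decisions wait for complete cycle-1
data), dose modifications within a cycle, multiple DLTs per patient, and
patient-level kinetic variability (the exposure model is a fixed, known
function of the schedule).  Passing tests therefore demonstrate correct
design behaviour under idealised accrual, not performance under real-world
operational drift.

## Known limitations

* The isotonic step of the bridge uses scipy's PAVA; its equivalence to
  the defining max-min formula is enforced by exhaustive enumeration over
  small count tables (all 4-level tables with ≤ 3 patients per level, all
  6-level tables with ≤ 2, and a seeded random sample of 6-level tables
  with ≤ 4) rather than the full 6-level space, which is ~7.5 million
  tables.
* The hierarchical MAP approximation is moment matching to one bivariate
  normal; heavy-tailed predictives would be truncated.  With a single
  completed schedule the data cannot inform `τ`, so the MAP prior's
  informativeness is essentially set by the `τ` prior — use the
  `tau_scales` argument deliberately.
* Grid quadrature spans ±8 (TITE-PK) / ±6 (BLRM) prior sds; data that push
  the posterior outside those ranges (pathological with the shipped
  priors) would be clipped.
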