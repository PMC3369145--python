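# Methods

## The multi-state model

Patients enter the cohort at their first recorded arthroplasty, which must
be a primary total hip (eligibility rule); time is measured in days since
that procedure. The shipped state space has ten states: first hip (1),
revision of the 1st arthroplasty (2), second hip (3), second knee (4), the
combinations "second hip + revision of 1st" (5) and "second knee + revision
of 1st" (6), revision of the 2nd hip (7) or knee (8), any further revision
of the 1st or 2nd arthroplasty (9), and dead (10, absorbing). Allowed moves
are 1→{2,3,4,10}, 2→{5,6,10}, 3→{5,7,10}, 4→{6,8,10}, 5..8→{9,10}, 9→10.
The graph is acyclic: a patient's path never revisits a state.

State assignment replays a patient's dated events against this structure.
Whether a revision belongs to the 1st or the 2nd arthroplasty is resolved by
joint+side identity, the same bookkeeping the SNAH `m` counter encodes. Two
deliberate choices:

* **Events the model cannot represent** (a third arthroplasty, a
  re-revision out of state 2 or 9) censor the path at the event's date. The
  alternative — mapping them into state 9 — was rejected because state 9 is
  defined as a *revision* of the 1st or 2nd arthroplasty, not an arbitrary
  further procedure.
* **Death after the administrative censoring date** counts as censoring,
  not an event: all follow-up stops at the fixed study-end date (default
  2008-12-31) after the last event.

Long-format preparation emits, per visited transient state, one row for
every allowed outgoing transition with a status flag on the realized one —
the counting-process layout used by R's `mstate`. A same-day state change
would create a zero-length sojourn no risk-set estimator can use; `Tstop`
is nudged by +0.5 day in that case, a distortion of half a day against a
day-resolution time scale.

## Nonparametric estimation

Nelson–Aalen increments are `d_qr(t)/n_q(t)` with the risk set counted just
before `t`; when a transition and a censoring share a time, censored
patients stay in the risk set (events-first convention). The
Aalen–Johansen estimator is the product integral of the increment matrices;
each factor `I + dA(u)` is row-stochastic by construction, so the row-sum
invariant holds to machine precision rather than by renormalisation.

Occupation probabilities are estimated on the **clock-forward** scale
(time since first arthroplasty) even though regression uses clock-reset
time: for state occupation probabilities the estimator remains consistent
for non-Markov processes under independent censoring, and the clock-forward
scale is the one on which "proportion of patients in state s at t years
after the first hip" is meaningful. Group-wise reporting combines states
5–9, which hold too few patients to be read separately; state 2 is reported
on its own. Variances for the occupation curves are not computed — point
estimates only.

## Transition-stratified Cox regression

Transition hazards are modelled as
`h_qr(t | Z) = h0_qr(t) · exp(β_qr' Z)` on **clock-reset** (sojourn) time:
a preliminary-analysis rationale for registry data is that time spent in
the current state, not time in previous states, drives the hazards
(semi-Markov). Stratifying on transitions with transition-specific
coefficients makes the stratified partial likelihood a product of
per-transition likelihoods with disjoint parameters, so the package fits
each transition separately; the factorization is verified numerically
against an independent stratified implementation (lifelines) in the test
suite. On the reset scale every at-risk interval starts at zero, so each
fit is an ordinary right-censored Cox fit on durations.

Numerical choices:

* **Ties**: Efron's correction, preferable to Breslow with the heavy ties
  produced by day-resolution times.
* **Optimisation**: Newton–Raphson from β = 0 with step-halving;
  convergence when max |score| < 1e-8, cap 50 iterations. A monotone
  (perfectly separating) likelihood is detected when the estimate escapes
  |β| > 15 and is flagged `monotone`, reported as non-converged rather than
  raised.
* **Inference**: Wald CIs and p-values from the inverse observed
  information. No robust or frailty variance: repeated transitions of one
  patient are treated as independent given the path, standard practice in
  transition-stratified registry analyses.
* **Age** enters as continuous years (centred handling is unnecessary for
  the fit itself); entry age group is a reporting stratification, fixed at
  cohort entry. Categorical age is available by passing indicator columns.
* **Skipping rules**: transitions with zero events, or with a constant
  covariate among at-risk rows, are skipped with a warning and marked "not
  estimable" in the hazard-ratio table.

Proportionality is checked per transition with Schoenfeld residuals
(Efron-consistent: within a tied group the risk-set mean averages the
Efron-adjusted denominators, so residuals sum to the score, zero at the
MLE) and the Grambsch–Therneau score test of zero slope of the scaled
residuals against transformed event time. The default transform is the
identity on clock-reset duration; a rank transform is available. The
statistic matches `cox.zph`-style implementations (cross-checked against
lifelines). Calibration caveat: with strongly right-skewed uncensored
event times the identity-transform test is conservative; under bounded
(administratively censored) follow-up — the registry setting — its size is
nominal, which is how the calibration simulation in the test suite is
designed.

## The registry simulator

`simulate_cohort` emulates the study conditions the analysis assumes:

* accrual uniform over 2002-01-01..2008-12-31, administrative censoring at
  2008-12-31 (all defaults configurable);
* sex male with probability 0.45 (hip-osteoarthritis cohorts skew female);
  entry age drawn from the three groups 55–64/65–74/75–84 with weights
  0.27/0.41/0.32 (the published cohort's distribution), uniform within a
  group;
* semi-Markov evolution by **latent clocks**: on entering a state, one
  sojourn time per allowed outgoing transition is drawn from its
  cause-specific hazard times `exp(β_sex·male + β_age·(age−70))`, and the
  earliest clock wins. For independent cause-specific hazards this is
  distributionally identical to sampling the total hazard and then the
  destination — the latent-clock form was chosen for clarity and because it
  makes the competing-risks identity (first-destination probabilities
  `λ_k/Σλ`) directly testable;
* hazards exponential by default; a Weibull family (shape k, cumulative
  hazard `m·(λt)^k`) exercises genuinely duration-dependent semi-Markov
  dynamics;
* each winning transition emits a dated registry event (contralateral hip
  for a second hip, random side for a knee, revision of whichever
  prosthesis the destination implies), so simulated cohorts round-trip
  through the SNAH codec and state-path assignment;
* event dates are rounded to whole days, reproducing registry resolution
  and its ties.

Default baseline rates (per person-year: 0.037 contralateral hip, 0.012
knee, 0.006 revision and 0.016 death out of state 1, smaller thereafter)
were chosen so a seven-year run yields the magnitudes seen in hip-first
registry cohorts — roughly 12% second hip, 4% knee, 2% revision, 5% dead —
and the default sex effects (e.g. HR 0.86 for the second hip, 1.59 for
death, males vs females) and mortality age gradient (+0.085 per year) are
of published-registry magnitude. The calibration is a convenience for
realistic defaults, not a claim reproduced by tests.

Reproducibility: patient `i` uses the substream
`numpy.random.default_rng((seed, i))` and consumes a fixed block of
uniforms, so cohorts are byte-identical for a fixed seed and patient `i`
is unchanged by cohort size or generation order.

**What the simulator does not emulate**: left truncation (patients whose
first arthroplasty predates the registry), calendar-time trends in rates,
prosthesis types, surgeon/hospital clustering, and dependent censoring.
Passing tests therefore validate the estimators and the pipeline under
independent censoring and correctly specified proportional hazards; they do
not certify behaviour under those real-data complications.

## Validation design and problem sizes

The test suite checks every estimator against an independent oracle:
brute-force risk-set counting for Nelson–Aalen; the hand-coded
product-limit formula and the classical cumulative-incidence estimator for
Aalen–Johansen reductions; a golden-section maximization of a hand-coded
Efron partial likelihood for Cox toys; lifelines for the stratified-fit
factorization and the PH-test statistic. Simulation studies use 200
replicates of 20,000-patient cohorts for CI coverage of known effects
(checked within the 65–74 entry group, where events are densest), 500
replicates for PH-test calibration, and 50,000 patients for the
competing-risks first-destination identity — sizes at which Monte-Carlo
error is small relative to the tolerances while the full suite stays
desk-scale.

## Known limitations

* The shipped SNAH grammar uses single-digit counters: histories with ten
  or more procedures raise a formatting error. The joint alphabet covers
  hips and knees; other joints can be supplied as a custom alphabet.
* Whether the `m` counter counts revisions per joint or per joint+side is
  ambiguous in prose descriptions of the notation; all published examples
  are consistent with joint+side, which is what the codec implements.
* Clock-forward Cox fits with delayed entry are not supported (the
  clock-reset model is the package's regression model; clock-forward fits
  are only available out of the initial state).
* Aalen–Johansen variance estimation and dependent-censoring estimators
  are out of scope.
* Knee-first cohorts need a custom eligibility rule and state semantics;
  the model spec is configurable but the shipped assignment logic is
  hip-first.
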