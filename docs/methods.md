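# Methods

## Decision problem

Two strategies for routine A1c monitoring of a primary-care cohort with
type 2 diabetes are compared from the municipal-payer perspective over a
10-year horizon: a point-of-care device at the care unit (immediate
results, US$8.48 cartridge per test plus a US$3,976.35 device) versus
testing at a centralized laboratory (US$2.65 per test, results delayed
weeks, and far fewer patients effectively tested).  The outcome currency
is the probability of achieving glycemic control (A1c ≤ 7.5%); no
quality-of-life weighting is applied.

## Markov cohort model

**States.** `uncontrolled`, `controlled`, four chronic complication states
(`cvd`, `retinopathy`, `nephropathy`, `diabetic_foot`), a transient
`hospitalization` state, and absorbing `dead`.  The whole cohort enters
`uncontrolled`.

**Cycles and transitions.** Cycle length is 3 months (the A1c reassessment
interval); the 10-year horizon gives 40 cycles plus the entry row.  Annual
probabilities *p* are converted to cycle probabilities by the
constant-hazard rule 1 − (1 − *p*)^(m/12).  Within a cycle the competing
events leaving a control state (reaching/losing control, each complication,
hospitalization, background death) are combined multiplicatively — the
probability of any event is 1 − ∏(1 − h<sub>i</sub>) — and allocated to the
individual events proportionally to their marginal hazards, so rows sum to
one exactly; a configuration whose naive hazard sum exceeds 1 is rejected
with the offending row named.  Chronic states persist until death;
hospitalization lasts one cycle and returns survivors to `uncontrolled`
(recurrence allowed).  Patients at target face complication hazards scaled
by the relative risk `complication_risk_rr_controlled`; relapse from
control and background (non-diabetes) mortality are available and default
to zero.

**Costs.** Alive patients incur one test per cycle at the strategy's unit
cost, with the device purchase amortized over a 5,000-test service life
(configurable).  The general diabetes care cost (US$1,844/patient/year)
accrues in the `uncontrolled` and `controlled` states; each complication
state accrues its own annual cost, interpreted as the all-inclusive annual
cost of caring for a patient with that complication.  The diabetic-foot
state cost is the mean of the three published sub-costs (healing, minor and
major amputation), 166.27.  State costs are scaled to the cycle length,
discounted at 4%/year at cycle boundaries (t = cycle·0.25 years), and
summed with a trapezoidal half-cycle correction (the average of adjacent
boundary rows), which always lies between the start-of-cycle and
end-of-cycle accrual conventions.

**Effectiveness.** Four definitions are selectable:

* `at_eval_point` — controlled-state occupancy at the evaluation cycle;
* `cumulative_ever` — probability of having ever reached control by the
  evaluation cycle (computed on a copy of the chain with `controlled` made
  absorbing, so relapse is not double-counted);
* `discounted_time_in_control` — discounted years spent in control over
  the horizon;
* `access_adjusted_attainment` (reference default) — the strategy's
  probability of an available A1c result times the discounted probability
  of first reaching the target at one of the quarterly assessments within
  the evaluation window:
  P(avail) · Σ<sub>j=1..W</sub> (1−p)^(j−1) · p · (1.04)^(−j/4).

The access-adjusted definition reflects that a patient cannot be
classified as at-target without a test result: the effectiveness gap
between strategies is driven as much by the testing-access gap (76% vs
36% of patients with results) as by the control-rate gap (0.14 vs 0.0738
per cycle).

## Reference calibration

The published analysis reports its results but not every structural choice
behind them, so the shipped reference configuration fixes two
under-determined quantities by calibration against the reported results;
both remain ordinary configuration values.

1. **Effectiveness definition and window.**  The reported effectiveness
   pair (0.35 point-of-care, 0.09 laboratory) has ratio 3.9, which no
   trace-based definition can produce from the control-rate ratio
   0.14/0.0738 = 1.9 alone; multiplying by the result-availability ratio
   0.76/0.36 closes the gap.  With a 12-month (4-cycle) window the
   access-adjusted definition gives 0.3366 and 0.0929 (−3.8% and +3.2%).
   A 6-month window — the literal reading of the published endpoint
   wording — yields 0.198/0.051 and is irreconcilable with the reported
   values under every definition tried.
2. **Complication risk under control.**  `complication_risk_rr_controlled
   = 0.3884` (a 61% risk reduction for patients at target) is the single
   calibrated structural parameter, solved so the incremental 10-year cost
   stays just below the US$2,000-per-effectiveness-unit crossing, keeping
   incremental net monetary benefit positive at that willingness-to-pay as
   reported.  The resulting strategy costs are 10,371.18 and 9,884.59
   (−1.3% and −1.1% from the reported 10,503.48 and 9,992.35), incremental
   cost 486.59 (−4.8% from 511.13) and ICER 1,996.61 (+2.5% from
   1,947.10).

Known deviations that no explored structure removes:

* **Incremental effectiveness.**  The reported triple (0.35, 0.09, 0.26)
  is internally consistent only at its printed rounding; the
  reconstruction's difference is 0.2437 (−6.3% from 0.26).  Pushing it
  above 0.247 requires breaking the 5% agreement of one of the component
  effectiveness values.
* **General-cost scope.**  Accruing the general care cost in every alive
  state (complication costs additive) produces 10-year costs near
  US$17,000 for both strategies and inverts the sign of the incremental
  cost; no setting of the risk ratio, relapse or background mortality
  repairs it.  The all-inclusive interpretation of complication costs is
  therefore used.
* **Tornado ranking.**  The published headline names nephropathy,
  retinopathy and CVD costs plus the hospitalization occurrence
  probability as the four most influential inputs.  Under this
  reconstruction the general care cost (width ≈ 222, via the survival
  differential between strategies) and the nephropathy occurrence
  probability (width ≈ 43, via chronic cost accrual per entrant) outrank
  hospitalization occurrence (width ≈ 12, a transient one-cycle event);
  the four named inputs appear at ranks 2, 4, 5 and 6 of 16.  Structures
  that promote hospitalization occurrence (per-admission costing,
  transient complications) destroy the cost agreement and were rejected.

## Sensitivity analyses

**Probabilistic.**  Each uncertain parameter gets an independent
distribution centred on its base value with sd = 20% of the mean
(overridable per parameter): beta for probabilities (method-of-moments),
gamma for costs, uniform and degenerate (`fixed`) also available.  The
default set covers the 16 literature parameters (five complication costs,
general cost, five occurrence and five case-fatality probabilities) plus
the per-cycle control probabilities and unit test/device costs.  Each of
the 1,000 trials (reproducible for a fixed seed) rebuilds the model and
re-evaluates both strategies; outputs are per-trial results, 2.5/97.5
percentile intervals, the cost-effectiveness plane, and the acceptability
curve over a US$0–5,000 willingness-to-pay grid.  The published percentile
bounds are not numeric targets here: the original sampling distributions
are unstated, so only qualitative behaviour (coverage of the base case,
majority of trials in the costlier-and-more-effective quadrant) is
checked.

**One-way (tornado).**  Each of the 16 literature parameters is swept to
±20% of base (the original ranges are unstated) with everything else at
base case; the outcome metric is incremental net monetary benefit at
WTP US$2,000 — not the ICER, which is unstable near Δeffect = 0 — and
parameters are ranked by descending width with alphabetical tie-break, so
the ordering is independent of input order.

## Synthetic cohort generator

The generator emulates the observed 18-month cohort at patient level:
exact group sizes (288/1,102), Bernoulli draws for sex, hypertension and
A1c result availability, normal ages, and a right-skewed baseline A1c.
A1c is log-normal with μ = log(median) matched exactly and σ fitted by
least squares to the two published quartiles (σ = 0.270 point-of-care,
0.378 laboratory); draws are clipped to the physiologic range 4–19.9%.
The published age dispersions (0.91, 0.55) are read as standard errors of
the mean — implausibly small for standard deviations — giving SDs of
15.44 and 18.26 years (SE·√n).  Time to control is a constant per-cycle
Bernoulli hazard over the 6-cycle follow-up, absorbing within the window;
patients without an available result are never assessed and never register
control.  Sex, availability and hypertension are mutually independent (no
joint structure is published).  The generator matches marginals only: it
does not reproduce between-group significance tests, appointment counts,
or any real-world correlation between access, age and control, so passing
cohort tests demonstrates correct emulation of the published summary
statistics, not validity on real patient data.

The control-rate estimator treats every person-cycle at risk as an
independent Bernoulli trial (valid under the constant-hazard generating
model): p̂ = events / person-cycles with a 95% Wilson score interval,
using assessable (result-available) patients only.  Coverage of the
generating values 0.14/0.0738 is verified over 200 seeded replicates at
n = 10,000 per group.

## Numerical choices and problem sizes

Matrix rows are validated to sum to 1 within 1e-12 and traces to conserve
mass within 1e-10.  ICERs are always computed from full-precision deltas
(the published 1,947.10 differs from 511.13/0.26 = 1,965.88 — presumed
rounding; recorded, not corrected).  Exact ties (Δcost = Δeffect = 0)
classify as no dominance.  Zero-mean parameters are held fixed in the PSA
(a zero-mean gamma/beta is degenerate).  Currency is 2020 US$ throughout;
files are written at full double precision.  Default problem sizes — 40
cycles, 1,000 Monte Carlo trials, 200 estimator replicates at n = 10,000 —
run in a few seconds on one CPU and are the package's standard working
sizes.

## Limitations

Cohort-level (not patient-level) simulation; no QALYs; no treatment
pathways; no patient travel/time costs; no correlation structure in the
PSA; complication states are mutually exclusive and absorbing, so
multimorbidity is not represented; background mortality defaults to zero,
so all-cause survival is optimistic; and the reconstruction of the
original model's unpublished structure is calibrated, not identified — the
deviations listed above bound what the agreement with the published
results does and does not establish.
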