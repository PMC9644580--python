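# Methods

## Decision problem and model structure

The package evaluates starting-treatment policies for stable coronary
artery disease with a cohort Markov model.  Three starting arms — optimal
medical therapy (OMT), stent PCI, and CABG — share one nine-state
structure: the three treatment states, one-cycle procedure states for
repeat PCI, maintenance states after each procedure (post-PCI,
post-CABG), long-term stable states after each procedure (stable PCI,
stable CABG), and an absorbing death state.  Post-procedure states exist
to carry the long-term medication costs and utilities that follow an
intervention; the stable states model patients who maintain their outcome
with high probability rather than transitioning further.  The allowed
arrow set is configuration data (`src/cadcea/data/default_model.yaml`),
not code: the clinical diagrams this topology abstracts admit more than
one reading, so users can edit the YAML to match their own.

Assumptions: first-order Markov dynamics (no memory beyond the current
state), time-homogeneous transition probabilities apart from the
mortality step, a closed cohort, and identical case-mix across starting
arms.

## Engine

Expected occupancy propagates as a row vector times per-cycle matrices —
expectation (cohort) propagation, not microsimulation; the cohort size of
10,000 sets the scale of the trace only, and results are reported per
patient.  Per cycle the engine:

1. adjusts each non-absorbing row's death probability by
   `increment * floor((cycle-1)/block)` (defaults 0.01 per 10 cycles:
   cycles 1–10 baseline, 11–20 +0.01), rescaling surviving entries to
   restore a row sum of 1 and capping death at 1.  This stepped additive
   probability is the literal reading of an "increase in death rate by
   0.01 every 10 cycles"; an additive-hazard mode
   (`mortality_mode="rate"`) is available since "rate" is ambiguous.  The
   rule replaces country/age/gender life tables with a configurable term.
2. accrues QALYs and recurring costs on the trapezoidal (life-table)
   average of consecutive occupancy vectors — the half-cycle correction —
   and one-time procedure costs on the expected inflow into each state
   that cycle.  A cohort that starts in a procedure state is charged that
   entry cost at time 0, undiscounted.
3. discounts all cycle flows by (1+r)^(−t) with r = 0.03/year and t the
   cycle mid-point in years (consistent with mid-cycle events); whether
   the original analyses discounted at boundaries or mid-points is
   generally unstated, so mid-point is the default and cycle-end applies
   when the half-cycle correction is off.

Degenerate inputs: rows must be stochastic within 1e-9; exactly one
absorbing state is required; a unit death row passes the mortality step
unchanged.  Conservation (rows summing to the cohort size within 1e-8)
and agreement with a start-vector × matrix-power oracle within 1e-10 are
enforced by tests.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| cycle length | 0.5 | years | treatment trajectories reviewed semi-annually |
| cycles | 20 | — | 10-year horizon |
| discount rate | 0.03 | /year | standard health-economics practice |
| WTP threshold | 80,000 | SGD/QALY | ≈ per-capita GDP |
| mortality increment | 0.01 per 10 cycles | probability | stepped ageing effect |
| PSA draws | 1000 | — | matches the analysis this reproduces |

Costs (SGD per 6 months, gamma): medication $129.86 (SD 36.06) with no
intervention, $147.68 (14.29) after a stent, $96.65 (30.03) after bypass;
one-time procedures $26,261.18 (4,908.53) for PCI/re-PCI and $35,756.64
(4,419.17) for CABG.  Utilities (beta): OMT 0.69 (0.12), PCI 0.72 (0.22),
re-PCI 0.70 (0.16), stable PCI 0.87 (0.03), CABG 0.82 (0.03), stable CABG
0.84 (0.04).  The maintenance states carry their procedure's utility and
post-procedure medication cost.  Both laws are stored by mean/SD and
converted to shapes by the method of moments (gamma: k = (m/s)²,
θ = s²/m; beta: a = m·κ, b = (1−m)·κ, κ = m(1−m)/s² − 1).  Published
beta *shape pairs* for some utilities are mutually inconsistent with
their published mean/SD (they imply different means); the mean/SD column
is treated as authoritative throughout and shapes are re-derived, never
transcribed.

Transition estimation pools one-step observation pairs over all patients
and cycles (a time-homogeneous maximum-likelihood proportion); a
stratified per-cycle estimator exists (`by_cycle=True`) but is off by
default.  Sample SDs use the n−1 denominator, with SD 0 by convention for
a single record.  Dirichlet uncertainty uses the raw tallies with a
configurable pseudo-count (default 0) for zero cells.  Horizon conversion
uses cumulative incidence, 1 − (1 − p)^(t/T), which assumes a constant
hazard within the source horizon; p = 1 maps to 1 rather than erroring.

## Synthetic records

The generator realises the Markov chain of the configured ground truth
for each patient and emits the same line-level schema the estimator
consumes (`patient_id, cycle, state`), plus billing records
(`patient_id, period, group, amount`).  Records stop at (and include)
entry into death, mirroring a repository that stops billing at death, so
the estimator is exercised on censoring-by-death; optional administrative
censoring (uniform over the window) mimics an extraction-window cut.
Medication amounts are gamma draws per patient-period, grouped by
procedure history (never intervened / after stent / after bypass, bypass
taking precedence); procedure entries emit a distinct `procedure`
category so billing-derived and config-derived costing can be
cross-checked.  Seeds are explicit fields; identical ground truth gives
byte-identical CSVs.

The shipped ground-truth matrix is synthetic.  Its stable-state entry
probabilities are the published 5-year event-free fractions 64/70
(bypass) and 43/72 (angioplasty) rescaled to 6 months (0.2178 and
0.0869); the remaining entries were chosen once as clinically plausible
values under which the CABG arm dominates on QALYs and the OMT arm on
cost.  What passing tests show is therefore that the *method* recovers
known inputs and orders policies correctly under that structure — not
that any real cohort exhibits these numbers.  The generator also omits
features of real data: visit-level granularity, covariate-dependent
transitions, cost inflation, and correlated billing noise.

## PSA and policy comparison

Each draw samples every gamma/beta parameter once and evaluates all five
policies — current practice (81.9/13.5/4.6% OMT/PCI/CABG), three 100%
policies, and the recommended 86% OMT / 14% CABG mix — with the same
draw (common random numbers), so incremental contrasts are not inflated
by independent sampling noise.  Transition rows can additionally be drawn
from their Dirichlet counts (`sample_transitions=True`); the default
varies costs and utilities only, matching the narrower uncertainty
statement the analysis is modelled on.  Uncertainty intervals are
equal-tailed 2.5–97.5 percentile intervals of the draws; ties (a delta of
exactly 0, as in self-comparison) count as neither cost-saving nor
cost-effective (strict inequalities).  Population scaling multiplies the
per-patient increments by an annual treated volume (default 6,000) and
values QALYs at the threshold.

## Reporting

Cohort summary tables use exact (Garwood, chi-square) Poisson intervals
for counts — the exact method reproduces published bounds (e.g.
13,294–13,751 for a count of 13,521) where the normal approximation is
off by one — and z-based normal intervals for means.  Category counts are
reported raw, never renormalised to close to 100%.  Full-precision values
are carried end to end; rounding happens only at display.  The pipeline
writes CSV outputs plus a JSON manifest (per-stage seeds derived from one
top-level seed, configuration hash, package version) from which every
emitted number is reproducible.

## Problem sizes and numerical choices

Default study conditions: 10,000 patients × 20 cycles for the synthetic
cohort and trace scale, 1000 PSA draws.  Tests use 50,000 patients for
transition recovery (three binomial standard errors per entry) and
smaller cohorts elsewhere; the acceptance script runs the full pipeline
at the default sizes.  Row-stochasticity tolerances are 1e-12 for
declared ground truth and 1e-9 for assembled models; oracle equivalence
is asserted at 1e-10 and closed-form accrual identities at 1e-12.

## Known limitations

- No semi-Markov sojourn times or tunnel states beyond what the topology
  encodes; no hazard-regression estimation of transitions.
- The per-state transition probabilities of the original clinical
  analysis are not public; its headline policy numbers are consequently
  not reproduction targets, only the in-model arithmetic and the
  qualitative direction of effect are.
- No EVPI or tornado analysis; plotting is limited to exporting
  plot-ready CSVs (CE plane, CEAC).
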