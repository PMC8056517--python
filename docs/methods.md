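# Methods

## Model structure

The engine is a deterministic Markov cohort model: expected state
fractions are propagated through per-cycle transition matrices, which is
the exact expectation of a microsimulation of any cohort size (the
published analysis's "100,000 patients" is treated as cohort
normalization).  Fourteen states: well on oral treatment, six acute
adverse-event (AE) states, five post-AE states, withdrawal to topical
diclofenac, and death.

Structural assumptions, and where they were genuinely open, the choice
made:

* **Acute AEs are one-cycle states.**  Survivors of symptomatic ulcer,
  complicated GI, stroke, MI, and heart failure stop the oral drug and move
  to the matching post state, where they remain until death.  Recurrence of
  severe GI events is captured economically — the post-GI per-cycle cost is
  the initial event cost weighted by the per-cycle recurrence probability
  (2.33% ulcer, 1.59% complicated GI) — not as a re-transition.
* **GI discomfort is transient and does not stop treatment.**  Each
  occurrence sends a fixed fraction of its occupants (13.9% on a
  traditional NSAID, 11.2% on a COX-2 inhibitor) to the withdrawn state;
  the rest face the same event/well distribution as the well state next
  cycle.  This reconciles "minor AE, no treatment stop" with the published
  withdrawal proportions.
* **Withdrawn and post-state patients face no further modelled AE risk.**
  They take topical diclofenac (its per-cycle cost is added to their state
  cost) and are exposed to background mortality — scaled, in post states,
  by a configurable excess hazard ratio (default 1, i.e. no excess; the
  supplementary mortality table of the source analysis is not public).
* **Competing risks compose independently**: death from an acute AE is
  1 − (1 − case fatality)(1 − background), and all relative risks multiply
  the *hazard*, not the probability, so any combination of multipliers
  keeps probabilities in [0, 1).
* **Discounting** uses discrete per-cycle factors (1+d)^(−0.25k) with
  cycle 0 undiscounted (5%/year for both costs and QALYs); **half-cycle
  correction** is the trapezoid average of adjacent occupancy vectors.
* **Post-state utilities** multiply the withdrawn baseline by default
  (post-state patients have stopped the oral drug); a config switch
  (`post_utility_baseline: on_treatment`) selects the other anchoring.

## Key parameters

| Parameter | Default | Units / note |
|---|---|---|
| Cycle length | 0.25 | years |
| Horizon | to age 80 | 100 cycles (low risk), 60 (high) |
| Discount rate (cost and QALY) | 0.05 | per year; DSA range 0–0.08 |
| Absolute AE rates (diclofenac) | 21.30 / 0.14 / 0.07 / 0.06 / 0.09 / 0.02 | % per observation period |
| Rate observation period | 1.0 | years (`absolute_rate_observation_years`) |
| High-risk multipliers | 2.96 (severe GI), 1.94 (CV) | hazard scale |
| Withdrawal fraction per GI-discomfort occurrence | 0.139 / 0.112 | NSAID / COX-2 |
| PSA dispersion | 20% of mean | SE, all sampled parameters |

The observation period of the absolute AE rates is an explicit
configuration field because the source tables do not state it.  The
default (annual) matches the annualized trial meta-reviews the rates come
from; setting 0.25 applies them per cycle.  The two readings change event
flux fourfold and hence absolute costs and QALYs substantially; the
qualitative decision structure (orderings, frontier, probabilistic
conclusions) is reported under the annual reading.

## Assumed supplementary inputs and calibration

The published analysis drew drug prices, OA management costs, background
mortality, AE case fatality, and the baseline utilities from supplementary
tables that are not publicly available.  The shipped config therefore
carries a clearly separated `supplementary_assumed` block.  Values were
chosen once, by calibration: plausible Chinese 2019 price and utility
ranges were searched for a point at which the deterministic base case
reproduces the published qualitative structure — cost and QALY ordering
diclofenac < diclofenac+PPI < imrecoxib < imrecoxib+PPI, all four
strategies on the frontier with strictly increasing sequential ICERs in
both risk groups, and an imrecoxib-vs-diclofenac ICER far below the
1× GDP-per-capita benchmark.  The chosen point (per 3-month cycle:
diclofenac $8, imrecoxib $21, omeprazole $11, OA management $2, topical
diclofenac $6; baseline utilities 0.72 on treatment / 0.55 withdrawn;
Gompertz background mortality 0.004·e^{0.09(age−55)}) was then frozen.

Because these are stand-ins, the model's *absolute* per-patient costs and
QALYs are not expected to match the published per-patient table; with this
state structure (absorbing withdrawal valued through a single utility
decrement) the published QALY gap pattern — 1.47 QALYs between diclofenac
and diclofenac+PPI but only 0.02–0.03 among the top three strategies — is
in fact unreachable at any parameter setting, because the withdrawal
fluxes fixed by the published rates keep the top-three gaps commensurate.
What the model does reproduce, and what the tests assert, is the decision
structure: the derived input-table cells exactly, the dominance structure
and orderings, near-certain cost-effectiveness of imrecoxib versus
diclofenac at $30,000/QALY, and the acceptability-curve hand-over order
(diclofenac → diclofenac+PPI → imrecoxib+PPI as willingness-to-pay rises).

## Uncertainty analysis

**One-way DSA** rebuilds the parameter set with a single substituted value
(±20%, or 0–8% for discount rates), re-derives all dependent quantities,
and re-runs every affected strategy.  Utilities and probabilities pushed
outside [0, 1] are clipped with a logged note rather than rejected, so a
±20% sweep over a 0.98 utility weight cannot crash the analysis.  Derived
quantities (indirect RRs, post-GI costs, resolved strategy specs) are not
swept directly; their primary inputs are.

**PSA** samples every uncertain scalar from a method-of-moments
distribution — gamma for costs (shape m²/s², scale s²/m), beta for
probabilities and utilities (SE capped below √(m(1−m)) to keep both shape
parameters positive; means of exactly 1 are degenerate and stay fixed),
lognormal for relative risks (σ² = ln(1+s²/m²)) — with all four strategies
evaluated on the same draw, so shared uncertainty (component RRs, event
costs, withdrawal fractions, drug prices) is preserved across arms.  Each
draw's RNG is seeded from (seed, draw index), making any draw reproducible
in isolation.  Invalid draws are resampled with a logged counter; more
than 1% aborts.

One deliberate re-parameterization: the withdrawn baseline utility is
stored and sampled as a *decrement* from the on-treatment baseline.
Sampling the two absolute levels independently at 20% SE makes their
difference — the quantity that drives every QALY comparison — switch sign
in a large fraction of draws, which no evidence supports; sampling the
treatment effect itself keeps the uncertainty on the quantity the trials
actually measure.

## Synthetic fixtures

`oacea.synthetic` generates complete parameter sets for testing: the
published input values are never randomized; only the supplementary block
is sampled, from configurable ranges bracketing the assumed defaults, with
Gompertz background mortality (two parameters: level at 55, log-hazard
slope).  Fixtures emulate the *structure* of real inputs — monotone adult
mortality, price ranges, utility ordering — but not their empirical
sources, so a passing test suite demonstrates correct model mechanics and
robustness of the qualitative conclusions across plausible inputs, not
agreement with any particular health system's data.

## Numerical choices

* Transition-matrix rows are validated to sum to 1 within 1e−12; cohort
  mass to 1e−9.  Row construction is vectorized over cycles (matrices vary
  only through age-specific mortality).
* ICERs are computed from unrounded model outputs; rounding is left to
  rendering.  The cheaper-and-worse (south-west) quadrant reports the
  numeric ratio with an explicit flag, since a bare ICER misleads there.
* Frontier: sort by cost (ties by name, logged), remove weakly dominated
  strategies, then iteratively remove interior strategies whose incoming
  sequential ICER is not strictly below their outgoing one.
* CEAC ties split a draw equally among the tied strategies.
* Default problem sizes: 5,000 PSA draws (the scale used throughout the
  tests and the acceptance script; the engine evaluates ~400 strategy-runs
  per second, so larger runs scale linearly), 100/60 cycles per the cohort
  design.

## Known limitations

* One AE per lifetime: no tunnel states or repeat events; severe-GI
  recurrence enters only through post-state costs.
* Withdrawal is absorbing; real patients switch among many alternatives.
* The PPI's effect is restricted to GI classes; adherence, PPI side
  effects, and dose titration are not modelled.
* Background mortality, case fatality, post-AE excess mortality, and all
  prices are assumed stand-ins (see above); absolute results should not be
  quoted as estimates for any real population without replacing the
  `supplementary_assumed` block.
* Equal analgesic efficacy across strategies is assumed throughout; QALY
  differences arise solely from adverse events and withdrawal.
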