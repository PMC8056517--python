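"""Markov cohort engine: transition matrices, cohort propagation, accrual.

The state space has 14 states: the on-treatment well state, six acute
adverse-event states (one cycle each), five lifelong post-AE states (GI
discomfort, being transient, has none), a withdrawn state (oral drug
stopped, topical diclofenac), and death.

Structural assumptions
----------------------
* An acute AE (other than GI discomfort) stops the oral drug: survivors
  move to the matching post state and remain there until death, with the
  recurrence burden of severe GI events captured through the
  recurrence-weighted post-state cost rather than re-transition.
* GI discomfort is transient: a fixed fraction withdraws to topical
  diclofenac, the rest face the same event/well distribution as the well
  state in the next cycle.
* Withdrawn and post-state patients face no further modelled AE risk.
* Background mortality applies everywhere; acute AE case fatality and
  background mortality combine as independent competing risks; post-state
  excess mortality scales the background hazard.

The cohort is propagated as expected state fractions (exact expectation of
a microsimulation of any cohort size).  Costs and QALYs are accrued with a
trapezoid half-cycle correction and per-cycle discounting at the annual
rates in the parameter set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    AE_CLASSES,
    ParameterSet,
    StrategySpec,
)

#: Model states in matrix order.
STATES: tuple[str, ...] = (
    "well_on_treatment",
    "gi_discomfort",
    "symptomatic_ulcer",
    "complicated_gi",
    "mi",
    "stroke",
    "hf",
    "post_symptomatic_ulcer",
    "post_complicated_gi",
    "post_mi",
    "post_stroke",
    "post_hf",
    "withdrawn_topical",
    "dead",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)

#: Acute AE classes that have a post state (all but GI discomfort).
POST_CLASSES = tuple(c for c in AE_CLASSES if c != "gi_discomfort")
ACUTE_INDEX = {c: S[c] for c in AE_CLASSES}
POST_INDEX = {c: S[f"post_{c}"] for c in POST_CLASSES}

ROW_SUM_TOL = 1e-12


class ModelConstructionError(ValueError):
    """A transition row could not be formed as a probability distribution."""


@dataclass
class CohortTrace:
    """State occupancy at each cycle boundary; row 0 is the start cohort."""

    occupancy: np.ndarray  # (n_cycles + 1, 14)
    start_age: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def ages(self, cycle_length_years: float = 0.25) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0]) * cycle_length_years


@dataclass
class StrategyResult:
    strategy_name: str
    mean_discounted_cost: float
    mean_discounted_qalys: float
    trace: CohortTrace

    @property
    def cost(self) -> float:
        return self.mean_discounted_cost

    @property
    def qalys(self) -> float:
        return self.mean_discounted_qalys


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

def _per_cycle_background_mortality(pset: ParameterSet) -> np.ndarray:
    """Per-cycle background death probability for cycles 0..n-1."""
    dt = pset.economics.cycle_length_years
    n = pset.risk_group.n_cycles
    ages = pset.risk_group.start_age + np.arange(n) * dt
    q_annual = np.array([pset.mortality.annual_mortality_at(a) for a in ages])
    return 1.0 - (1.0 - q_annual) ** dt


def _annual_background_mortality(pset: ParameterSet) -> np.ndarray:
    n = pset.risk_group.n_cycles
    dt = pset.economics.cycle_length_years
    ages = pset.risk_group.start_age + np.arange(n) * dt
    return np.array([pset.mortality.annual_mortality_at(a) for a in ages])


def transition_matrices(
    pset: ParameterSet, strategy: StrategySpec | str
) -> np.ndarray:
    """All per-cycle transition matrices, shape (n_cycles, 14, 14).

    Matrices vary across cycles only through age-dependent background
    mortality.  Every row is validated to be a probability distribution.
    """
    if isinstance(strategy, str):
        strategy = pset.strategies[strategy]
    n = pset.risk_group.n_cycles
    dt = pset.economics.cycle_length_years

    p_bg = _per_cycle_background_mortality(pset)  # (n,)
    q_annual = _annual_background_mortality(pset)
    p_ae = {c: pset.per_cycle_event_probability(strategy, c) for c in AE_CLASSES}
    total_ae = sum(p_ae.values())
    if total_ae > 1.0:
        raise ModelConstructionError(
            f"{strategy.name}: per-cycle AE probabilities sum to "
            f"{total_ae:.4f} > 1 in the well row"
        )

    M = np.zeros((n, N_STATES, N_STATES))
    surv = 1.0 - p_bg  # (n,)

    # well_on_treatment: background death, then the AE/well distribution.
    w = S["well_on_treatment"]
    M[:, w, S["dead"]] = p_bg
    for c in AE_CLASSES:
        M[:, w, ACUTE_INDEX[c]] = surv * p_ae[c]
    M[:, w, w] = surv * (1.0 - total_ae)

    # gi_discomfort: transient.  Survivors either withdraw or re-enter the
    # well-state event/well distribution.
    g = S["gi_discomfort"]
    wf = strategy.withdrawal_fraction
    M[:, g, S["dead"]] = p_bg
    M[:, g, S["withdrawn_topical"]] = surv * wf
    for c in AE_CLASSES:
        M[:, g, ACUTE_INDEX[c]] += surv * (1.0 - wf) * p_ae[c]
    M[:, g, w] = surv * (1.0 - wf) * (1.0 - total_ae)

    # Acute AE states: case fatality and background mortality compete
    # independently; survivors move to the post state.
    for c in POST_CLASSES:
        a = ACUTE_INDEX[c]
        cf = pset.mortality.ae_case_fatality[c]
        p_die = 1.0 - (1.0 - cf) * surv
        M[:, a, S["dead"]] = p_die
        M[:, a, POST_INDEX[c]] = 1.0 - p_die

    # Post states: background mortality scaled by the excess hazard ratio
    # on the rate scale; survivors stay put.
    for c in POST_CLASSES:
        p = POST_INDEX[c]
        hr = pset.mortality.post_state_excess_hazard_ratio.get(c, 1.0)
        p_die = 1.0 - (1.0 - q_annual) ** (dt * hr)
        M[:, p, S["dead"]] = p_die
        M[:, p, p] = 1.0 - p_die

    # Withdrawn: background mortality only.
    wd = S["withdrawn_topical"]
    M[:, wd, S["dead"]] = p_bg
    M[:, wd, wd] = surv

    # Dead: absorbing.
    M[:, S["dead"], S["dead"]] = 1.0

    _validate_matrices(M)
    return M


def build_transition_matrix(
    pset: ParameterSet, strategy: StrategySpec | str, cycle_index: int
) -> np.ndarray:
    """The 14x14 transition matrix applying over cycle ``cycle_index``."""
    n = pset.risk_group.n_cycles
    if not 0 <= cycle_index < n:
        raise ModelConstructionError(
            f"cycle_index {cycle_index} outside [0, {n})"
        )
    return transition_matrices(pset, strategy)[cycle_index]


def _validate_matrices(M: np.ndarray) -> None:
    if M.min() < -ROW_SUM_TOL or M.max() > 1.0 + 1e-9:
        bad = np.unravel_index(int(np.argmin(M)), M.shape)
        raise ModelConstructionError(
            f"transition probability outside [0, 1] at (cycle, from, to) = "
            f"{bad}: {M[bad]}"
        )
    row_sums = M.sum(axis=2)
    err = np.abs(row_sums - 1.0)
    if err.max() > ROW_SUM_TOL:
        k, i = np.unravel_index(int(np.argmax(err)), err.shape)
        raise ModelConstructionError(
            f"row {STATES[i]!r} of cycle-{k} matrix sums to {row_sums[k, i]!r}"
        )


# ---------------------------------------------------------------------------
# Cohort propagation and accrual
# ---------------------------------------------------------------------------

def run_cohort(pset: ParameterSet, strategy: StrategySpec | str) -> CohortTrace:
    """Propagate the full cohort (fraction 1 in the well state at cycle 0)
    through all cycles: occupancy[k+1] = occupancy[k] @ M(k)."""
    M = transition_matrices(pset, strategy)
    n = pset.risk_group.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0, S["well_on_treatment"]] = 1.0
    for k in range(n):
        occ[k + 1] = occ[k] @ M[k]
    if occ.min() < -1e-12 or occ.max() > 1.0 + 1e-9:
        raise ModelConstructionError("cohort occupancy left [0, 1]")
    return CohortTrace(occupancy=occ, start_age=pset.risk_group.start_age)


def state_cost_vector(pset: ParameterSet, strategy: StrategySpec | str) -> np.ndarray:
    """Per-cycle cost (2019 USD) of residing in each state."""
    if isinstance(strategy, str):
        strategy = pset.strategies[strategy]
    c = pset.costs
    v = np.zeros(N_STATES)
    on_treatment = c.oa_management_cost_per_cycle + strategy.drug_cost_per_cycle
    v[S["well_on_treatment"]] = on_treatment
    v[S["gi_discomfort"]] = on_treatment + c.initial_state_cost["gi_discomfort"]
    for cls in POST_CLASSES:
        v[ACUTE_INDEX[cls]] = c.initial_state_cost[cls]
        v[POST_INDEX[cls]] = (
            c.post_state_cost[cls] + c.topical_diclofenac_cost_per_cycle
        )
    v[S["withdrawn_topical"]] = c.topical_diclofenac_cost_per_cycle
    return v


def state_utility_vector(pset: ParameterSet, strategy: StrategySpec | str) -> np.ndarray:
    """Annual utility of each state (QALY accrual multiplies by cycle length)."""
    u = pset.utilities
    v = np.zeros(N_STATES)
    post_base = (
        u.baseline_withdrawn
        if u.post_baseline == "withdrawn"
        else u.baseline_on_treatment
    )
    v[S["well_on_treatment"]] = u.baseline_on_treatment
    v[S["gi_discomfort"]] = u.baseline_on_treatment * u.weight_initial["gi_discomfort"]
    for cls in POST_CLASSES:
        v[ACUTE_INDEX[cls]] = u.baseline_on_treatment * u.weight_initial[cls]
        v[POST_INDEX[cls]] = post_base * u.weight_post[cls]
    v[S["withdrawn_topical"]] = u.baseline_withdrawn
    return v


def accrue_outcomes(
    trace: CohortTrace, pset: ParameterSet, strategy: StrategySpec | str
) -> StrategyResult:
    """Discounted, half-cycle-corrected mean cost and QALYs per patient.

    Cycle k (k = 0 .. n-1) contributes the trapezoid-averaged occupancy
    (occ[k] + occ[k+1]) / 2, valued at the per-cycle state costs and
    utilities and discounted by (1 + d)^(-dt k); cycle 0 is undiscounted.
    """
    if isinstance(strategy, str):
        strategy = pset.strategies[strategy]
    n = pset.risk_group.n_cycles
    if trace.occupancy.shape != (n + 1, N_STATES):
        raise ValueError(
            f"trace shape {trace.occupancy.shape} does not match "
            f"{(n + 1, N_STATES)}"
        )
    dt = pset.economics.cycle_length_years
    hcc = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])  # (n, 14)
    k = np.arange(n)
    disc_cost = (1.0 + pset.economics.annual_discount_rate_cost) ** (-dt * k)
    disc_qaly = (1.0 + pset.economics.annual_discount_rate_qaly) ** (-dt * k)
    cost_v = state_cost_vector(pset, strategy)
    util_v = state_utility_vector(pset, strategy)
    cost = float(disc_cost @ (hcc @ cost_v))
    qalys = float(disc_qaly @ (hcc @ util_v) * dt)
    return StrategyResult(
        strategy_name=strategy.name,
        mean_discounted_cost=cost,
        mean_discounted_qalys=qalys,
        trace=trace,
    )


def evaluate_strategy(pset: ParameterSet, strategy: StrategySpec | str) -> StrategyResult:
    """run_cohort + accrue_outcomes for one strategy."""
    if isinstance(strategy, str):
        strategy = pset.strategies[strategy]
    trace = run_cohort(pset, strategy)
    return accrue_outcomes(trace, pset, strategy)


def evaluate_all(pset: ParameterSet) -> dict[str, StrategyResult]:
    """Evaluate every strategy in the parameter set on the same scenario."""
    return {name: evaluate_strategy(pset, name) for name in pset.strategies}


def trace_to_frame(trace: CohortTrace, cycle_length_years: float = 0.25):
    """Cohort trace as a pandas DataFrame (age column + one column per state)."""
    import pandas as pd

    df = pd.DataFrame(trace.occupancy, columns=list(STATES))
    df.insert(0, "age", trace.ages(cycle_length_years))
    return df
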