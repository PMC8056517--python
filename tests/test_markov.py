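"""Transition-matrix construction, cohort propagation, and accrual."""
import numpy as np
import pytest

from oacea import markov as M
from oacea.params import AE_CLASSES

from conftest import make_toy_pset


def brute_force_occupancy(matrices: np.ndarray) -> np.ndarray:
    """Path-enumeration oracle: occupancy at each cycle boundary as the sum
    of probabilities of every explicit state path starting in the well
    state.  Exponential in cycle count; use for <= 3 cycles."""
    n = matrices.shape[0]
    n_states = matrices.shape[1]
    occ = np.zeros((n + 1, n_states))
    start = M.S["well_on_treatment"]
    paths = [((start,), 1.0)]
    occ[0, start] = 1.0
    for k in range(n):
        new_paths = []
        for path, w in paths:
            frm = path[-1]
            for to in range(n_states):
                p = matrices[k, frm, to]
                if p > 0.0:
                    new_paths.append((path + (to,), w * p))
        paths = new_paths
        for path, w in paths:
            occ[k + 1, path[-1]] += w
    return occ


class TestTransitionMatrix:
    def test_no_events_no_mortality_freezes_live_states(self, low_pset):
        pset = make_toy_pset(
            low_pset, rates={}, mortality=0.0, case_fatality=0.0
        )
        mat = M.build_transition_matrix(pset, "diclofenac", 0)
        # non-transient states hold their occupants; transient states
        # resolve deterministically (acute -> post, discomfort -> well or
        # withdrawn)
        hold = [
            M.S[s]
            for s in ("well_on_treatment", "withdrawn_topical", "dead")
        ] + list(M.POST_INDEX.values())
        for i in hold:
            assert mat[i, i] == 1.0
        for cls in M.POST_CLASSES:
            assert mat[M.ACUTE_INDEX[cls], M.POST_INDEX[cls]] == 1.0
        g = M.S["gi_discomfort"]
        assert mat[g, M.S["withdrawn_topical"]] == pytest.approx(0.139)
        assert mat[g, M.S["well_on_treatment"]] == pytest.approx(0.861)

    def test_background_mortality_converted_per_cycle(self, low_pset):
        q = 0.02
        pset = make_toy_pset(low_pset, rates={}, mortality=q)
        mat = M.build_transition_matrix(pset, "diclofenac", 0)
        w, d = M.S["well_on_treatment"], M.S["dead"]
        assert mat[w, d] == pytest.approx(1 - (1 - q) ** 0.25, rel=1e-12)
        assert mat[w, w] == pytest.approx((1 - q) ** 0.25, rel=1e-12)

    @pytest.mark.parametrize("strategy", ["diclofenac", "imrecoxib_ppi"])
    @pytest.mark.parametrize("group", ["low", "high"])
    def test_rows_are_distributions_and_dead_absorbing(
        self, low_pset, high_pset, strategy, group
    ):
        pset = low_pset if group == "low" else high_pset
        mats = M.transition_matrices(pset, strategy)
        assert np.all(mats >= 0) and np.all(mats <= 1)
        assert np.allclose(mats.sum(axis=2), 1.0, atol=1e-12)
        dead = M.S["dead"]
        assert np.all(mats[:, dead, dead] == 1.0)

    def test_acute_states_route_to_matching_post_state(self, low_pset):
        mat = M.build_transition_matrix(low_pset, "diclofenac", 0)
        for cls in M.POST_CLASSES:
            a, p = M.ACUTE_INDEX[cls], M.POST_INDEX[cls]
            assert mat[a, p] > 0
            # acute states go nowhere except their post state or death
            others = [
                j for j in range(M.N_STATES) if j not in (p, M.S["dead"])
            ]
            assert np.all(mat[a, others] == 0)

    def test_withdrawal_fraction_routes_gi_discomfort(self, low_pset):
        pset = make_toy_pset(low_pset, rates={}, mortality=0.0)
        mat = M.build_transition_matrix(pset, "diclofenac", 0)
        g, wd = M.S["gi_discomfort"], M.S["withdrawn_topical"]
        assert mat[g, wd] == pytest.approx(0.139)
        assert mat[g, M.S["well_on_treatment"]] == pytest.approx(1 - 0.139)

    def test_cycle_index_bounds(self, low_pset):
        with pytest.raises(M.ModelConstructionError):
            M.build_transition_matrix(low_pset, "diclofenac", 100)


class TestRunCohort:
    def test_two_cycle_mi_toy(self, low_pset):
        # only event: MI at per-cycle probability 0.1, no deaths.
        pset = make_toy_pset(
            low_pset, rates={"mi": 0.1}, n_cycles=2, mortality=0.0,
            case_fatality=0.0,
        )
        pset.economics.absolute_rate_observation_years = 0.25
        trace = M.run_cohort(pset, "diclofenac")
        occ = trace.occupancy[2]
        assert occ[M.S["well_on_treatment"]] == pytest.approx(0.81)
        assert occ[M.S["mi"]] == pytest.approx(0.09)
        assert occ[M.S["post_mi"]] == pytest.approx(0.10)

    @pytest.mark.parametrize("strategy", ["diclofenac", "imrecoxib"])
    def test_mass_conserved_and_dead_nondecreasing(self, high_pset, strategy):
        trace = M.run_cohort(high_pset, strategy)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, M.S["dead"]]
        assert np.all(np.diff(dead) >= -1e-15)
        assert trace.occupancy[0, M.S["well_on_treatment"]] == 1.0

    @pytest.mark.parametrize("strategy", ["diclofenac", "imrecoxib_ppi"])
    def test_matches_path_enumeration_oracle(self, low_pset, strategy):
        pset = make_toy_pset(low_pset, n_cycles=3)
        mats = M.transition_matrices(pset, strategy)
        trace = M.run_cohort(pset, strategy)
        oracle = brute_force_occupancy(mats)
        assert np.allclose(trace.occupancy, oracle, atol=1e-12)


class TestAccrual:
    def test_one_undiscounted_life_year(self, low_pset):
        pset = make_toy_pset(
            low_pset, rates={}, n_cycles=4, mortality=0.0, discount=0.0,
            baseline_on_treatment=1.0, decrement=0.0,
        )
        result = M.evaluate_strategy(pset, "diclofenac")
        assert result.mean_discounted_qalys == pytest.approx(1.0, rel=1e-12)

    def test_discount_factors_per_cycle(self, low_pset):
        pset = make_toy_pset(
            low_pset, rates={}, n_cycles=4, mortality=0.0, discount=0.05,
            baseline_on_treatment=1.0, decrement=0.0,
        )
        result = M.evaluate_strategy(pset, "diclofenac")
        factors = [1.05 ** (-0.25 * k) for k in range(4)]
        assert factors == pytest.approx([1.0, 0.98788, 0.97590, 0.96407], abs=5e-6)
        assert result.mean_discounted_qalys == pytest.approx(
            0.25 * sum(factors), rel=1e-12
        )

    def test_cost_annuity_closed_form(self, low_pset):
        # no events, no mortality: discounted cost is the annuity of the
        # per-cycle on-treatment cost.
        pset = make_toy_pset(low_pset, rates={}, mortality=0.0)
        result = M.evaluate_strategy(pset, "imrecoxib")
        per_cycle = (
            pset.costs.oa_management_cost_per_cycle
            + pset.strategies["imrecoxib"].drug_cost_per_cycle
        )
        d = pset.economics.annual_discount_rate_cost
        annuity = per_cycle * sum(
            (1 + d) ** (-0.25 * k) for k in range(pset.risk_group.n_cycles)
        )
        assert result.mean_discounted_cost == pytest.approx(annuity, rel=1e-12)

    def test_half_cycle_correction_identity_on_constant_trace(self, low_pset):
        pset = make_toy_pset(low_pset, rates={}, n_cycles=8, mortality=0.0)
        trace = M.run_cohort(pset, "diclofenac")
        # constant occupancy: HCC average equals the occupancy itself
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_dimension_mismatch_rejected(self, low_pset):
        trace = M.run_cohort(low_pset, "diclofenac")
        short = M.CohortTrace(trace.occupancy[:50], trace.start_age)
        with pytest.raises(ValueError):
            M.accrue_outcomes(short, low_pset, "diclofenac")


class TestMonotonicity:
    def test_scaling_ae_rates_down_never_decreases_qalys(self, low_pset):
        qalys = []
        for scale in (1.0, 0.5, 0.1, 0.0):
            pset = make_toy_pset(
                low_pset,
                rates={
                    c: scale * low_pset.diclofenac_absolute_rate[c]
                    for c in AE_CLASSES
                },
            )
            qalys.append(M.evaluate_strategy(pset, "diclofenac").qalys)
        assert all(b >= a - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_zero_cost_ppi_never_reduces_qalys(self, low_pset):
        base = M.evaluate_strategy(low_pset, "diclofenac")
        import copy

        pset = copy.deepcopy(low_pset)
        pset.drug_cost_per_cycle["omeprazole"] = 0.0
        pset.refresh_derived()
        with_ppi = M.evaluate_strategy(pset, "diclofenac_ppi")
        assert with_ppi.qalys >= base.qalys

    def test_zero_cost_ppi_reduces_gi_burden_cost(self, low_pset):
        # isolate adverse-event costs: no drug/management/topical costs and
        # no CV risk, so the PPI's only effect is the GI protection.  (With
        # CV risk included, longer on-treatment exposure under PPI can raise
        # CV costs — an exposure-time interaction, not a GI effect.)
        import copy

        pset = copy.deepcopy(low_pset)
        pset.drug_cost_per_cycle = {k: 0.0 for k in pset.drug_cost_per_cycle}
        pset.costs.oa_management_cost_per_cycle = 0.0
        pset.costs.topical_diclofenac_cost_per_cycle = 0.0
        for c in ("stroke", "mi", "hf"):
            pset.diclofenac_absolute_rate[c] = 0.0
        pset.refresh_derived()
        base = M.evaluate_strategy(pset, "diclofenac")
        with_ppi = M.evaluate_strategy(pset, "diclofenac_ppi")
        assert with_ppi.qalys >= base.qalys
        assert with_ppi.cost <= base.cost

    def test_zero_discount_yields_most_qalys(self, low_pset):
        qalys = []
        for d in (0.0, 0.03, 0.05, 0.08):
            pset = make_toy_pset(low_pset, discount=d)
            qalys.append(M.evaluate_strategy(pset, "imrecoxib").qalys)
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))
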