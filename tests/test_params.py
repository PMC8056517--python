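"""Parameter primitives, loading, derivation, and validation."""
import copy
import math

import pytest
import yaml
from hypothesis import given, settings, strategies as st

from oacea import params as P

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class TestIndirectRR:
    @pytest.mark.parametrize(
        "rr_ab, rr_bc, expected",
        [
            # imrecoxib-vs-celecoxib chained with celecoxib-vs-diclofenac
            (0.50, 0.66, 0.33),
            (1.36, 0.43, 0.5848),
            (0.50, 0.68, 0.34),
        ],
    )
    def test_published_chain(self, rr_ab, rr_bc, expected):
        assert P.indirect_rr(rr_ab, rr_bc) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(0.01, 10.0))
    def test_identity(self, x):
        assert P.indirect_rr(1.0, x) == pytest.approx(x)

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 10))
    def test_associative_commutative(self, a, b, c):
        lhs = P.indirect_rr(P.indirect_rr(a, b), c)
        rhs = P.indirect_rr(a, P.indirect_rr(c, b))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.5])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(P.ValidationError):
            P.indirect_rr(bad, 1.0)

    def test_full_derived_row_matches_published(self, low_pset):
        derived = low_pset.strategies["imrecoxib"].rr_vs_diclofenac
        published = {
            "gi_discomfort": 0.33,
            "symptomatic_ulcer": 0.58,
            "complicated_gi": 0.34,
            "stroke": 0.51,
            "mi": 1.40,
            "hf": 1.42,
        }
        for cls, expected in published.items():
            assert round(derived[cls], 2) == expected


class TestRateToProbability:
    def test_quarter_year_conversion(self):
        # hand evaluation: r = -ln(1 - 0.2130), P2 = 1 - exp(-r/4)
        assert P.rate_to_probability(0.2130, 1.0, 0.25) == pytest.approx(
            0.0581, abs=5e-5
        )

    @given(st.floats(0.0, 0.99), st.floats(0.01, 10))
    def test_identity_when_periods_match(self, p, t):
        assert P.rate_to_probability(p, t, t) == pytest.approx(p, abs=1e-12)

    def test_zero_rate(self):
        assert P.rate_to_probability(0.0, 1.0, 7.3) == 0.0

    @given(st.floats(0.001, 0.98))
    def test_inverse_consistency(self, p):
        down = P.rate_to_probability(p, 1.0, 0.25)
        assert P.rate_to_probability(down, 0.25, 1.0) == pytest.approx(
            p, abs=1e-12
        )

    @given(
        st.floats(0.001, 0.5), st.floats(0.002, 0.5),
        st.floats(0.1, 2.0), st.floats(0.15, 2.5),
    )
    def test_monotone_in_p_and_t(self, p1, dp, t2, dt):
        base = P.rate_to_probability(p1, 1.0, t2)
        assert P.rate_to_probability(p1 + dp, 1.0, t2) > base
        assert P.rate_to_probability(p1, 1.0, t2 + dt) > base

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_rejects_invalid_probability(self, bad):
        with pytest.raises(P.ValidationError):
            P.rate_to_probability(bad, 1.0, 0.25)


class TestCurrencyAdjustment:
    def test_2019_is_exchange_only(self):
        assert P.adjust_cost_to_2019_usd(6898.5, 2019) == pytest.approx(1000.0)

    def test_chained_cpi(self):
        # 100 RMB in 2016 prices: x 1.016 x 1.021 x 1.029, / 6.8985
        expected = 100 * 1.016 * 1.021 * 1.029 / 6.8985
        assert P.adjust_cost_to_2019_usd(100.0, 2016) == pytest.approx(expected)
        assert expected == pytest.approx(15.47, abs=5e-3)

    def test_zero(self):
        assert P.adjust_cost_to_2019_usd(0.0, 2017) == 0.0

    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.sampled_from(range(2015, 2020)))
    def test_linear(self, a, b, year):
        assert P.adjust_cost_to_2019_usd(a + b, year) == pytest.approx(
            P.adjust_cost_to_2019_usd(a, year) + P.adjust_cost_to_2019_usd(b, year),
            abs=1e-6,
        )

    def test_rejects_year_outside_series(self):
        with pytest.raises(P.ValidationError):
            P.adjust_cost_to_2019_usd(100.0, 2014)


class TestPostGiCost:
    @pytest.mark.parametrize(
        "initial, rate, expected, tol",
        [
            (34.57, 0.0233, 0.81, 0.01),
            # printed table shows 21.54; 1-cent rounding discrepancy tolerated
            (1354.15, 0.0159, 21.54, 0.011),
            (123.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_recurrence_weighted_cost(self, initial, rate, expected, tol):
        assert P.derive_post_gi_cost(initial, rate) == pytest.approx(
            expected, abs=tol + 1e-12
        )

    def test_derived_values_in_loaded_set(self, low_pset):
        assert low_pset.costs.post_state_cost["symptomatic_ulcer"] == pytest.approx(
            0.81, abs=0.01
        )
        assert low_pset.costs.post_state_cost["complicated_gi"] == pytest.approx(
            21.54, abs=0.011
        )


class TestLoading:
    def test_default_config_loads_and_validates(self, low_pset, high_pset):
        assert set(low_pset.strategies) == set(P.STRATEGY_NAMES)
        assert low_pset.risk_group.start_age == 55
        assert low_pset.risk_group.n_cycles == 100
        assert high_pset.risk_group.gi_risk_multiplier == 2.96
        assert high_pset.risk_group.cv_risk_multiplier == 1.94

    def test_round_trip(self, tmp_path, low_pset):
        path = tmp_path / "roundtrip.yaml"
        low_pset.save(path)
        reloaded = P.load_parameter_set(path)
        assert reloaded == low_pset

    @pytest.mark.parametrize(
        "path, value",
        [
            (("paper_table1", "initial_state_cost", "mi"), -1.0),
            (("paper_table1", "rr_celecoxib_vs_diclofenac", "hf"), 0.0),
            (("paper_table1", "utility_weight_initial", "stroke"), 1.4),
            (("paper_table1", "recurrence_rate", "complicated_gi"), -0.2),
            (("design", "withdrawal_fraction", "cox2_inhibitor"), 1.7),
            (("supplementary_assumed", "ae_case_fatality", "mi"), 1.0),
            (("design", "economics", "annual_discount_rate_qaly"), 0.2),
        ],
    )
    def test_corrupted_config_rejected(self, path, value):
        with open(P.default_config_path()) as fh:
            cfg = yaml.safe_load(fh)
        node = cfg
        for key in path[:-1]:
            node = node[key]
        node[path[-1]] = value
        with pytest.raises(P.ValidationError):
            P.ParameterSet.from_config(cfg)

    def test_missing_supplementary_entry_filled_with_warning(self, caplog):
        with open(P.default_config_path()) as fh:
            cfg = yaml.safe_load(fh)
        del cfg["supplementary_assumed"]["ae_case_fatality"]
        with caplog.at_level("WARNING", logger="oacea.params"):
            pset = P.ParameterSet.from_config(cfg)
        assert "ae_case_fatality" in caplog.text
        assert pset.mortality.ae_case_fatality["mi"] > 0

    def test_ppi_rr_is_one_without_ppi(self, low_pset):
        for cls in P.AE_CLASSES:
            assert low_pset.strategies["diclofenac"].ppi_rr[cls] == 1.0
            assert low_pset.strategies["imrecoxib"].ppi_rr[cls] == 1.0

    def test_ppi_rr_unity_on_cv_classes(self, low_pset):
        for name in ("diclofenac_ppi", "imrecoxib_ppi"):
            for cls in P.CV_CLASSES:
                assert low_pset.strategies[name].ppi_rr[cls] == 1.0


class TestParameterPaths:
    def test_get_set_roundtrip(self, low_pset):
        pset = copy.deepcopy(low_pset)
        for path, _ in P.parameter_inventory(pset):
            value = P.get_path(pset, path)
            P.set_path(pset, path, value * 1.0)
            assert P.get_path(pset, path) == value

    def test_unknown_path_rejected(self, low_pset):
        with pytest.raises(P.ValidationError):
            P.get_path(low_pset, "costs.initial_state_cost.nonexistent")
        with pytest.raises(P.ValidationError):
            P.set_path(copy.deepcopy(low_pset), "nope.nope", 1.0)

    def test_refresh_propagates_shared_components(self, low_pset):
        pset = copy.deepcopy(low_pset)
        P.set_path(pset, "rr_imrecoxib_vs_celecoxib.mi", 2.0)
        pset.refresh_derived()
        expected = 2.0 * pset.rr_celecoxib_vs_diclofenac["mi"]
        for name in ("imrecoxib", "imrecoxib_ppi"):
            assert pset.strategies[name].rr_vs_diclofenac["mi"] == pytest.approx(
                expected
            )


class TestEventProbability:
    def test_risk_multipliers_apply_to_severe_classes_only(
        self, low_pset, high_pset
    ):
        for cls in ("symptomatic_ulcer", "complicated_gi"):
            rate_lo = P.probability_to_rate(
                low_pset.per_cycle_event_probability("diclofenac", cls), 0.25
            )
            rate_hi = P.probability_to_rate(
                high_pset.per_cycle_event_probability("diclofenac", cls), 0.25
            )
            assert rate_hi / rate_lo == pytest.approx(2.96, rel=1e-9)
        rate_lo = P.probability_to_rate(
            low_pset.per_cycle_event_probability("diclofenac", "gi_discomfort"), 0.25
        )
        rate_hi = P.probability_to_rate(
            high_pset.per_cycle_event_probability("diclofenac", "gi_discomfort"), 0.25
        )
        assert rate_hi == pytest.approx(rate_lo, rel=1e-12)

    def test_probability_matches_closed_form(self, low_pset):
        p = low_pset.per_cycle_event_probability("diclofenac", "gi_discomfort")
        assert p == pytest.approx(1 - (1 - 0.2130) ** 0.25, rel=1e-12)
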