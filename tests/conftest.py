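import copy

import pytest

from oacea.params import ParameterSet, default_parameter_set


@pytest.fixture(scope="session")
def low_pset() -> ParameterSet:
    return default_parameter_set("low")


@pytest.fixture(scope="session")
def high_pset() -> ParameterSet:
    return default_parameter_set("high")


def make_toy_pset(
    base: ParameterSet,
    *,
    rates: dict[str, float] | None = None,
    n_cycles: int | None = None,
    mortality: float | None = None,
    case_fatality: float | None = None,
    discount: float | None = None,
    baseline_on_treatment: float | None = None,
    decrement: float | None = None,
) -> ParameterSet:
    """Copy of ``base`` with simplified dynamics for closed-form checks.

    ``rates`` replaces the diclofenac absolute rates (unlisted classes are
    zeroed); ``mortality`` sets a flat annual background mortality;
    ``n_cycles`` shortens the horizon (start age adjusted to keep the
    end-at-80 contract).
    """
    pset = copy.deepcopy(base)
    if rates is not None:
        pset.diclofenac_absolute_rate = {
            c: rates.get(c, 0.0) for c in pset.diclofenac_absolute_rate
        }
    if n_cycles is not None:
        pset.risk_group.n_cycles = n_cycles
        pset.risk_group.start_age = 80.0 - n_cycles * pset.economics.cycle_length_years
    if mortality is not None:
        pset.mortality.background_annual_mortality = {
            a: mortality for a in range(50, 81)
        }
    if case_fatality is not None:
        pset.mortality.ae_case_fatality = {
            c: case_fatality for c in pset.mortality.ae_case_fatality
        }
    if discount is not None:
        pset.economics.annual_discount_rate_cost = discount
        pset.economics.annual_discount_rate_qaly = discount
    if baseline_on_treatment is not None:
        pset.utilities.baseline_on_treatment = baseline_on_treatment
    if decrement is not None:
        pset.utilities.withdrawal_utility_decrement = decrement
    pset.refresh_derived()
    pset.validate()
    return pset
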