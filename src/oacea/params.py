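"""Parameter model for the osteoarthritis NSAID/COX-2 cost-utility analysis.

The model compares four treatment strategies for chronic osteoarthritis pain
management — diclofenac, diclofenac + omeprazole (PPI), imrecoxib, and
imrecoxib + omeprazole — on their lifetime cost and QALY consequences of six
adverse-event (AE) classes: three gastrointestinal (GI discomfort,
symptomatic ulcer, complicated GI) and three cardiovascular (stroke, MI,
heart failure).

This module holds every input of one scenario (:class:`ParameterSet`), the
primitive transformations used to derive inputs (indirect relative-risk
chaining, rate/probability conversion, CPI + exchange-rate adjustment), and
YAML (de)serialization.  All monetary values are 2019 USD after loading.
"""
from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

# Adverse-event classes, in the canonical table order.  The first three are
# gastrointestinal, the last three cardiovascular.
AE_CLASSES: tuple[str, ...] = (
    "gi_discomfort",
    "symptomatic_ulcer",
    "complicated_gi",
    "stroke",
    "mi",
    "hf",
)
GI_CLASSES: tuple[str, ...] = AE_CLASSES[:3]
CV_CLASSES: tuple[str, ...] = AE_CLASSES[3:]
#: GI classes subject to the high-risk-group multiplier (ulcer/complicated
#: GI only; transient GI discomfort is not escalated in older patients).
SEVERE_GI_CLASSES: tuple[str, ...] = ("symptomatic_ulcer", "complicated_gi")

STRATEGY_NAMES: tuple[str, ...] = (
    "diclofenac",
    "diclofenac_ppi",
    "imrecoxib",
    "imrecoxib_ppi",
)

# Year-on-year Chinese consumer price index factors used to express historic
# RMB costs in 2019 prices, and the 2019 RMB-per-USD exchange rate.
CPI_FACTORS: dict[int, float] = {
    2015: 1.014,
    2016: 1.020,
    2017: 1.016,
    2018: 1.021,
    2019: 1.029,
}
RMB_PER_USD_2019: float = 6.8985


class ValidationError(ValueError):
    """A parameter value or combination violates the model's contracts."""


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def indirect_rr(rr_a_vs_b: float, rr_b_vs_c: float) -> float:
    """Chain two relative risks through a common comparator.

    Under the transitivity assumption of an indirect treatment comparison,
    RR(A vs C) = RR(A vs B) * RR(B vs C).  Used to obtain imrecoxib-vs-
    diclofenac relative risks from imrecoxib-vs-celecoxib and
    celecoxib-vs-diclofenac trial evidence.
    """
    if rr_a_vs_b <= 0 or rr_b_vs_c <= 0:
        raise ValidationError(
            f"relative risks must be positive, got {rr_a_vs_b}, {rr_b_vs_c}"
        )
    return rr_a_vs_b * rr_b_vs_c


def rate_to_probability(p1: float, t1: float, t2: float) -> float:
    """Re-express a probability observed over period ``t1`` on period ``t2``.

    Assumes a constant instantaneous event rate r = -ln(1 - p1) / t1, so the
    probability over ``t2`` is P2 = 1 - exp(-r t2) = 1 - (1 - p1)^(t2/t1).
    """
    if not 0.0 <= p1 < 1.0:
        raise ValidationError(f"p1 must be in [0, 1), got {p1}")
    if t1 <= 0 or t2 <= 0:
        raise ValidationError(f"durations must be positive, got {t1}, {t2}")
    return -math.expm1(math.log1p(-p1) * t2 / t1)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Instantaneous rate underlying probability ``p`` over duration ``t``."""
    if not 0.0 <= p < 1.0:
        raise ValidationError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValidationError(f"duration must be positive, got {t}")
    return -math.log1p(-p) / t


def adjust_cost_to_2019_usd(amount_rmb: float, year: int) -> float:
    """Inflate a year-``year`` RMB amount to 2019 prices and convert to USD.

    CPI factors for the years strictly after ``year`` through 2019 are
    chained, then the amount is divided by the 2019 exchange rate
    (6.8985 RMB/USD).
    """
    years = sorted(CPI_FACTORS)
    if year not in CPI_FACTORS:
        raise ValidationError(
            f"year {year} outside the CPI series {years[0]}-{years[-1]}"
        )
    factor = 1.0
    for y in years:
        if y > year:
            factor *= CPI_FACTORS[y]
    return amount_rmb * factor / RMB_PER_USD_2019


def derive_post_gi_cost(initial_cost: float, recurrence_rate: float) -> float:
    """Per-cycle maintenance cost of a post-GI state.

    GI events carry no continuous maintenance cost, but a per-cycle
    recurrence risk; the expected per-cycle cost is the initial event cost
    weighted by the recurrence probability.
    """
    if initial_cost < 0 or recurrence_rate < 0:
        raise ValidationError("initial cost and recurrence rate must be >= 0")
    return initial_cost * recurrence_rate


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StrategySpec:
    """Fully resolved description of one treatment strategy.

    ``rr_vs_diclofenac`` and ``ppi_rr`` are final per-class multipliers on
    the diclofenac event rate; ``drug_cost_per_cycle`` includes the PPI
    cost when ``has_ppi``.
    """

    name: str
    drug_class: str  # "traditional_nsaid" | "cox2_inhibitor"
    has_ppi: bool
    rr_vs_diclofenac: dict[str, float]
    ppi_rr: dict[str, float]
    withdrawal_fraction: float
    drug_cost_per_cycle: float

    def validate(self) -> None:
        if self.drug_class not in ("traditional_nsaid", "cox2_inhibitor"):
            raise ValidationError(
                f"strategy {self.name}: unknown drug class {self.drug_class!r}"
            )
        for table_name, table in (
            ("rr_vs_diclofenac", self.rr_vs_diclofenac),
            ("ppi_rr", self.ppi_rr),
        ):
            _require_classes(table, f"strategies.{self.name}.{table_name}")
            for cls, v in table.items():
                if v <= 0:
                    raise ValidationError(
                        f"strategies.{self.name}.{table_name}.{cls}: "
                        f"relative risk must be > 0, got {v}"
                    )
        if not self.has_ppi and any(
            self.ppi_rr[c] != 1.0 for c in AE_CLASSES
        ):
            raise ValidationError(
                f"strategies.{self.name}.ppi_rr must be 1.0 without a PPI"
            )
        for c in CV_CLASSES:
            if self.ppi_rr[c] != 1.0:
                raise ValidationError(
                    f"strategies.{self.name}.ppi_rr.{c}: a PPI does not "
                    "modify cardiovascular risk (must be 1.0)"
                )
        if not 0.0 <= self.withdrawal_fraction <= 1.0:
            raise ValidationError(
                f"strategies.{self.name}.withdrawal_fraction must be in "
                f"[0, 1], got {self.withdrawal_fraction}"
            )
        if self.drug_cost_per_cycle < 0:
            raise ValidationError(
                f"strategies.{self.name}.drug_cost_per_cycle must be >= 0"
            )


@dataclass
class EconomicsSpec:
    annual_discount_rate_cost: float = 0.05
    annual_discount_rate_qaly: float = 0.05
    cycle_length_years: float = 0.25
    #: Observation period (years) over which the absolute AE probabilities
    #: were measured; they are converted to per-cycle probabilities through
    #: the constant-rate transform.  0.25 treats them as per-cycle.
    absolute_rate_observation_years: float = 0.25
    threshold_grid: list[float] = field(default_factory=lambda: default_threshold_grid())

    def validate(self) -> None:
        for name in ("annual_discount_rate_cost", "annual_discount_rate_qaly"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.08:
                raise ValidationError(
                    f"economics.{name} must be in [0, 0.08], got {v}"
                )
        if self.cycle_length_years <= 0:
            raise ValidationError("economics.cycle_length_years must be > 0")
        if self.absolute_rate_observation_years <= 0:
            raise ValidationError(
                "economics.absolute_rate_observation_years must be > 0"
            )
        grid = self.threshold_grid
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError(
                "economics.threshold_grid must be strictly ascending"
            )


def default_threshold_grid() -> list[float]:
    """WTP grid: fine below $5,000 (where strategy cross-overs occur),
    coarser up to the 3x-GDP-per-capita threshold of $30,000/QALY."""
    return [float(x) for x in range(0, 5001, 100)] + [
        float(x) for x in range(5500, 30001, 500)
    ]


@dataclass
class RiskGroup:
    """Patient subgroup: cohort start age and baseline AE risk scaling.

    The high-risk group (start age 65) carries a 2.96-fold risk of
    ulcer/complicated GI events and a 1.94-fold risk of CV events.
    The horizon always runs to age 80 in 3-month cycles.
    """

    name: str
    start_age: float
    n_cycles: int
    gi_risk_multiplier: float = 1.0
    cv_risk_multiplier: float = 1.0

    def validate(self, cycle_length_years: float = 0.25) -> None:
        if self.n_cycles <= 0:
            raise ValidationError("risk_group.n_cycles must be positive")
        end_age = self.start_age + self.n_cycles * cycle_length_years
        if abs(end_age - 80.0) > 1e-9:
            raise ValidationError(
                f"risk_group {self.name}: horizon must end at age 80, "
                f"got {end_age}"
            )
        if self.gi_risk_multiplier < 1.0 or self.cv_risk_multiplier < 1.0:
            raise ValidationError(
                f"risk_group {self.name}: risk multipliers must be >= 1"
            )


@dataclass
class CostTable:
    """Per-cycle state costs in 2019 USD.

    ``post_state_cost`` for the two severe GI classes is derived as
    initial cost x per-cycle recurrence rate; CV post-state maintenance
    costs are direct inputs.
    """

    initial_state_cost: dict[str, float]
    post_state_cost: dict[str, float]
    oa_management_cost_per_cycle: float
    topical_diclofenac_cost_per_cycle: float
    recurrence_rate: dict[str, float]

    def validate(self) -> None:
        _require_classes(self.initial_state_cost, "costs.initial_state_cost")
        for cls in AE_CLASSES[1:]:
            if cls not in self.post_state_cost:
                raise ValidationError(f"costs.post_state_cost.{cls} missing")
        for name, table in (
            ("initial_state_cost", self.initial_state_cost),
            ("post_state_cost", self.post_state_cost),
        ):
            for cls, v in table.items():
                if v < 0:
                    raise ValidationError(
                        f"costs.{name}.{cls} must be >= 0, got {v}"
                    )
        if self.oa_management_cost_per_cycle < 0:
            raise ValidationError("costs.oa_management_cost_per_cycle must be >= 0")
        if self.topical_diclofenac_cost_per_cycle < 0:
            raise ValidationError(
                "costs.topical_diclofenac_cost_per_cycle must be >= 0"
            )
        for cls in SEVERE_GI_CLASSES:
            if cls not in self.recurrence_rate:
                raise ValidationError(f"costs.recurrence_rate.{cls} missing")
            r = self.recurrence_rate[cls]
            if not 0.0 <= r <= 1.0:
                raise ValidationError(
                    f"costs.recurrence_rate.{cls} must be in [0, 1], got {r}"
                )
            expected = derive_post_gi_cost(self.initial_state_cost[cls], r)
            if abs(self.post_state_cost[cls] - expected) > 0.01:
                raise ValidationError(
                    f"costs.post_state_cost.{cls} must equal initial cost x "
                    f"recurrence rate ({expected:.4f}), got "
                    f"{self.post_state_cost[cls]}"
                )


@dataclass
class UtilityTable:
    """Utility weights, anchored at 1 = OA patient on treatment without AEs.

    ``baseline_on_treatment`` is the absolute utility of that anchor.  The
    utility after stopping the oral drug (topical diclofenac fallback) is
    stored as ``withdrawal_utility_decrement``, the oral drug's utility
    advantage, so that uncertainty analyses perturb the treatment effect
    itself rather than two strongly correlated absolute levels;
    ``baseline_withdrawn`` exposes the resulting absolute utility.
    ``post_baseline`` selects which baseline multiplies the post-state
    weights (withdrawn by default, since post-state patients have stopped
    the oral drug).
    """

    weight_initial: dict[str, float]
    weight_post: dict[str, float]
    baseline_on_treatment: float
    withdrawal_utility_decrement: float
    post_baseline: str = "withdrawn"

    @property
    def baseline_withdrawn(self) -> float:
        return max(self.baseline_on_treatment - self.withdrawal_utility_decrement, 0.0)

    def validate(self) -> None:
        _require_classes(self.weight_initial, "utilities.weight_initial")
        _require_classes(self.weight_post, "utilities.weight_post")
        for name, table in (
            ("weight_initial", self.weight_initial),
            ("weight_post", self.weight_post),
        ):
            for cls, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"utilities.{name}.{cls} must be in [0, 1], got {v}"
                    )
        for cls in AE_CLASSES:
            if self.weight_post[cls] < self.weight_initial[cls]:
                raise ValidationError(
                    f"utilities.weight_post.{cls} must be >= weight_initial"
                )
        if not 0.0 <= self.baseline_on_treatment <= 1.0:
            raise ValidationError(
                f"utilities.baseline_on_treatment must be in [0, 1], got "
                f"{self.baseline_on_treatment}"
            )
        if not 0.0 <= self.withdrawal_utility_decrement <= 1.0:
            raise ValidationError(
                f"utilities.withdrawal_utility_decrement must be in [0, 1], "
                f"got {self.withdrawal_utility_decrement}"
            )
        if self.post_baseline not in ("withdrawn", "on_treatment"):
            raise ValidationError(
                f"utilities.post_baseline must be 'withdrawn' or "
                f"'on_treatment', got {self.post_baseline!r}"
            )


@dataclass
class MortalitySpec:
    """Background mortality and AE-specific death risks.

    ``background_annual_mortality`` maps integer age to the annual death
    probability of the general population; ``ae_case_fatality`` is the
    probability of dying from an acute AE during its event cycle;
    ``post_state_excess_hazard_ratio`` scales the background mortality
    hazard in post-AE states (1 = no excess).
    """

    background_annual_mortality: dict[int, float]
    ae_case_fatality: dict[str, float]
    post_state_excess_hazard_ratio: dict[str, float]

    def validate(self) -> None:
        ages = sorted(self.background_annual_mortality)
        if not ages:
            raise ValidationError("mortality.background_annual_mortality empty")
        prev = None
        for a in ages:
            q = self.background_annual_mortality[a]
            if not 0.0 <= q < 1.0:
                raise ValidationError(
                    f"mortality.background_annual_mortality.{a} must be in "
                    f"[0, 1), got {q}"
                )
            if 55 <= a <= 80 and prev is not None and q < prev - 1e-12:
                raise ValidationError(
                    f"mortality.background_annual_mortality must be "
                    f"nondecreasing over ages 55-80 (age {a})"
                )
            if 55 <= a <= 80:
                prev = q
        _require_classes(self.ae_case_fatality, "mortality.ae_case_fatality")
        for cls, v in self.ae_case_fatality.items():
            if not 0.0 <= v < 1.0:
                raise ValidationError(
                    f"mortality.ae_case_fatality.{cls} must be in [0, 1), got {v}"
                )
        for cls, v in self.post_state_excess_hazard_ratio.items():
            if v < 1.0:
                raise ValidationError(
                    f"mortality.post_state_excess_hazard_ratio.{cls} must be "
                    f">= 1, got {v}"
                )

    def annual_mortality_at(self, age: float) -> float:
        """Annual background death probability at (possibly fractional) age,
        clamped to the table's range."""
        table = self.background_annual_mortality
        ages = sorted(table)
        a = int(math.floor(age))
        a = min(max(a, ages[0]), ages[-1])
        return table[a]


@dataclass
class ParameterSet:
    """All inputs of one scenario (one risk group, four strategies).

    Shared evidence components (component relative risks, PPI effects,
    withdrawal fractions, drug acquisition costs) are stored once and the
    four :class:`StrategySpec` objects are derived from them by
    :meth:`refresh_derived`, so that sensitivity analyses perturb the
    underlying evidence and every strategy sees the same perturbed value.
    """

    economics: EconomicsSpec
    risk_group: RiskGroup
    costs: CostTable
    utilities: UtilityTable
    mortality: MortalitySpec
    diclofenac_absolute_rate: dict[str, float]
    rr_celecoxib_vs_diclofenac: dict[str, float]
    rr_imrecoxib_vs_celecoxib: dict[str, float]
    ppi_rr_traditional: dict[str, float]
    ppi_rr_cox2: dict[str, float]
    withdrawal_fraction: dict[str, float]
    drug_cost_per_cycle: dict[str, float]
    strategies: dict[str, StrategySpec] = field(default_factory=dict)

    # -- derivation ---------------------------------------------------------

    def refresh_derived(self) -> None:
        """Recompute every derived quantity from the primary inputs:
        indirect imrecoxib-vs-diclofenac RRs, post-GI maintenance costs,
        and the four resolved strategy specifications."""
        for cls in SEVERE_GI_CLASSES:
            self.costs.post_state_cost[cls] = derive_post_gi_cost(
                self.costs.initial_state_cost[cls],
                self.costs.recurrence_rate[cls],
            )
        rr_imre = {
            c: indirect_rr(
                self.rr_imrecoxib_vs_celecoxib[c],
                self.rr_celecoxib_vs_diclofenac[c],
            )
            for c in AE_CLASSES
        }
        ones = {c: 1.0 for c in AE_CLASSES}
        ppi_trad = {**ones, **{c: self.ppi_rr_traditional[c] for c in GI_CLASSES}}
        ppi_cox2 = {**ones, **{c: self.ppi_rr_cox2[c] for c in GI_CLASSES}}
        w_trad = self.withdrawal_fraction["traditional_nsaid"]
        w_cox2 = self.withdrawal_fraction["cox2_inhibitor"]
        c_dic = self.drug_cost_per_cycle["diclofenac"]
        c_imre = self.drug_cost_per_cycle["imrecoxib"]
        c_ppi = self.drug_cost_per_cycle["omeprazole"]
        self.strategies = {
            "diclofenac": StrategySpec(
                "diclofenac", "traditional_nsaid", False,
                dict(ones), dict(ones), w_trad, c_dic,
            ),
            "diclofenac_ppi": StrategySpec(
                "diclofenac_ppi", "traditional_nsaid", True,
                dict(ones), ppi_trad, w_trad, c_dic + c_ppi,
            ),
            "imrecoxib": StrategySpec(
                "imrecoxib", "cox2_inhibitor", False,
                dict(rr_imre), dict(ones), w_cox2, c_imre,
            ),
            "imrecoxib_ppi": StrategySpec(
                "imrecoxib_ppi", "cox2_inhibitor", True,
                dict(rr_imre), ppi_cox2, w_cox2, c_imre + c_ppi,
            ),
        }

    def validate(self) -> None:
        self.economics.validate()
        self.risk_group.validate(self.economics.cycle_length_years)
        self.costs.validate()
        self.utilities.validate()
        self.mortality.validate()
        _require_classes(
            self.diclofenac_absolute_rate,
            "diclofenac_absolute_rate",
        )
        for cls, p in self.diclofenac_absolute_rate.items():
            if not 0.0 <= p < 1.0:
                raise ValidationError(
                    f"diclofenac_absolute_rate.{cls} must be in "
                    f"[0, 1), got {p}"
                )
        for name, table in (
            ("rr_celecoxib_vs_diclofenac", self.rr_celecoxib_vs_diclofenac),
            ("rr_imrecoxib_vs_celecoxib", self.rr_imrecoxib_vs_celecoxib),
        ):
            _require_classes(table, name)
            for cls, v in table.items():
                if v <= 0:
                    raise ValidationError(f"{name}.{cls} must be > 0, got {v}")
        for name, table in (
            ("ppi_rr_traditional", self.ppi_rr_traditional),
            ("ppi_rr_cox2", self.ppi_rr_cox2),
        ):
            for cls in GI_CLASSES:
                if cls not in table:
                    raise ValidationError(f"{name}.{cls} missing")
                if table[cls] <= 0:
                    raise ValidationError(f"{name}.{cls} must be > 0")
        for k in ("traditional_nsaid", "cox2_inhibitor"):
            if k not in self.withdrawal_fraction:
                raise ValidationError(f"withdrawal_fraction.{k} missing")
            w = self.withdrawal_fraction[k]
            if not 0.0 <= w <= 1.0:
                raise ValidationError(
                    f"withdrawal_fraction.{k} must be in [0, 1], got {w}"
                )
        for k in ("diclofenac", "imrecoxib", "omeprazole"):
            if k not in self.drug_cost_per_cycle:
                raise ValidationError(f"drug_cost_per_cycle.{k} missing")
            if self.drug_cost_per_cycle[k] < 0:
                raise ValidationError(f"drug_cost_per_cycle.{k} must be >= 0")
        if set(self.strategies) != set(STRATEGY_NAMES):
            raise ValidationError(
                f"strategies must be exactly {STRATEGY_NAMES}"
            )
        for s in self.strategies.values():
            s.validate()

    # -- event probabilities ------------------------------------------------

    def risk_multiplier(self, ae_class: str) -> float:
        if ae_class in SEVERE_GI_CLASSES:
            return self.risk_group.gi_risk_multiplier
        if ae_class in CV_CLASSES:
            return self.risk_group.cv_risk_multiplier
        return 1.0

    def per_cycle_event_probability(
        self, strategy: StrategySpec | str, ae_class: str
    ) -> float:
        """Per-cycle probability of an AE of ``ae_class`` for a patient on
        treatment under ``strategy``.

        Relative risks (strategy vs diclofenac, PPI effect) and the risk-
        group multiplier compose on the rate scale: the diclofenac absolute
        probability (observed over ``absolute_rate_observation_years``) is
        converted to an instantaneous rate, scaled, and converted back to a
        probability over one cycle.  Rate-scale composition treats trial
        RRs as hazard ratios and keeps the result in [0, 1) for any
        positive multiplier.
        """
        if isinstance(strategy, str):
            strategy = self.strategies[strategy]
        p_obs = self.diclofenac_absolute_rate[ae_class]
        rate = probability_to_rate(
            p_obs, self.economics.absolute_rate_observation_years
        )
        rate *= (
            strategy.rr_vs_diclofenac[ae_class]
            * strategy.ppi_rr[ae_class]
            * self.risk_multiplier(ae_class)
        )
        return -math.expm1(-rate * self.economics.cycle_length_years)

    # -- (de)serialization --------------------------------------------------

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_config(self) -> dict:
        """Dump to the three-block config layout (design / paper_table1 /
        supplementary_assumed).  Derived quantities are not written; they
        are recomputed on load."""
        return {
            "design": {
                "economics": {
                    "annual_discount_rate_cost": self.economics.annual_discount_rate_cost,
                    "annual_discount_rate_qaly": self.economics.annual_discount_rate_qaly,
                    "cycle_length_years": self.economics.cycle_length_years,
                    "absolute_rate_observation_years": self.economics.absolute_rate_observation_years,
                    "threshold_grid": list(self.economics.threshold_grid),
                },
                "risk_group": asdict(self.risk_group),
                "withdrawal_fraction": dict(self.withdrawal_fraction),
            },
            "paper_table1": {
                "initial_state_cost": dict(self.costs.initial_state_cost),
                "post_state_cost_cv": {
                    c: self.costs.post_state_cost[c] for c in CV_CLASSES
                },
                "recurrence_rate": dict(self.costs.recurrence_rate),
                "utility_weight_initial": dict(self.utilities.weight_initial),
                "utility_weight_post": dict(self.utilities.weight_post),
                "diclofenac_absolute_rate": dict(
                    self.diclofenac_absolute_rate
                ),
                "rr_celecoxib_vs_diclofenac": dict(self.rr_celecoxib_vs_diclofenac),
                "rr_imrecoxib_vs_celecoxib": dict(self.rr_imrecoxib_vs_celecoxib),
                "ppi_rr": {
                    "traditional_nsaid": {
                        c: self.ppi_rr_traditional[c] for c in GI_CLASSES
                    },
                    "cox2_inhibitor": {
                        c: self.ppi_rr_cox2[c] for c in GI_CLASSES
                    },
                },
            },
            "supplementary_assumed": {
                "drug_cost_per_cycle": dict(self.drug_cost_per_cycle),
                "oa_management_cost_per_cycle": self.costs.oa_management_cost_per_cycle,
                "topical_diclofenac_cost_per_cycle": self.costs.topical_diclofenac_cost_per_cycle,
                "baseline_utility": {
                    "on_treatment": self.utilities.baseline_on_treatment,
                    "withdrawn": self.utilities.baseline_withdrawn,
                },
                "post_utility_baseline": self.utilities.post_baseline,
                "ae_case_fatality": dict(self.mortality.ae_case_fatality),
                "post_state_excess_hazard_ratio": dict(
                    self.mortality.post_state_excess_hazard_ratio
                ),
                "background_annual_mortality": dict(
                    self.mortality.background_annual_mortality
                ),
            },
        }

    @classmethod
    def from_config(
        cls, config: Mapping, risk_group: str | None = None
    ) -> "ParameterSet":
        """Build a validated ParameterSet from a config mapping.

        The config may carry either a single ``design.risk_group`` or a
        ``design.risk_groups`` table keyed by group name, in which case
        ``risk_group`` selects one ('low' by default).  Missing entries in
        the ``supplementary_assumed`` block are filled from the packaged
        defaults with a warning.
        """
        config = copy.deepcopy(dict(config))
        design = _require(config, "design")
        t1 = _require(config, "paper_table1")
        supp = dict(config.get("supplementary_assumed") or {})

        from .synthetic import default_supplementary_block  # cycle-free at call time

        defaults = default_supplementary_block()
        for key, value in defaults.items():
            if key not in supp:
                logger.warning(
                    "supplementary_assumed.%s missing from config; using the "
                    "packaged assumed default", key,
                )
                supp[key] = value

        econ_cfg = dict(design.get("economics") or {})
        if "threshold_grid" not in econ_cfg or econ_cfg["threshold_grid"] is None:
            econ_cfg["threshold_grid"] = default_threshold_grid()
        economics = EconomicsSpec(
            annual_discount_rate_cost=float(econ_cfg.get("annual_discount_rate_cost", 0.05)),
            annual_discount_rate_qaly=float(econ_cfg.get("annual_discount_rate_qaly", 0.05)),
            cycle_length_years=float(econ_cfg.get("cycle_length_years", 0.25)),
            absolute_rate_observation_years=float(
                econ_cfg.get("absolute_rate_observation_years", 0.25)
            ),
            threshold_grid=[float(x) for x in econ_cfg["threshold_grid"]],
        )

        if "risk_group" in design:
            rg_cfg = design["risk_group"]
        else:
            groups = _require(design, "risk_groups")
            name = risk_group or "low"
            if name not in groups:
                raise ValidationError(
                    f"design.risk_groups has no group {name!r}"
                )
            rg_cfg = dict(groups[name], name=name)
        rg = RiskGroup(
            name=str(rg_cfg.get("name", risk_group or "low")),
            start_age=float(_require(rg_cfg, "start_age", "design.risk_group")),
            n_cycles=int(_require(rg_cfg, "n_cycles", "design.risk_group")),
            gi_risk_multiplier=float(rg_cfg.get("gi_risk_multiplier", 1.0)),
            cv_risk_multiplier=float(rg_cfg.get("cv_risk_multiplier", 1.0)),
        )

        costs = CostTable(
            initial_state_cost=_class_map(t1, "initial_state_cost", AE_CLASSES),
            post_state_cost=_class_map(t1, "post_state_cost_cv", CV_CLASSES),
            oa_management_cost_per_cycle=float(
                _require(supp, "oa_management_cost_per_cycle", "supplementary_assumed")
            ),
            topical_diclofenac_cost_per_cycle=float(
                _require(supp, "topical_diclofenac_cost_per_cycle", "supplementary_assumed")
            ),
            recurrence_rate=_class_map(t1, "recurrence_rate", SEVERE_GI_CLASSES),
        )
        baseline = _require(supp, "baseline_utility", "supplementary_assumed")
        u_on = float(_require(baseline, "on_treatment", "baseline_utility"))
        u_wd = float(_require(baseline, "withdrawn", "baseline_utility"))
        if u_wd > u_on:
            raise ValidationError(
                "baseline_utility.withdrawn must not exceed on_treatment"
            )
        utilities = UtilityTable(
            weight_initial=_class_map(t1, "utility_weight_initial", AE_CLASSES),
            weight_post=_class_map(t1, "utility_weight_post", AE_CLASSES),
            baseline_on_treatment=u_on,
            withdrawal_utility_decrement=u_on - u_wd,
            post_baseline=str(supp.get("post_utility_baseline", "withdrawn")),
        )
        mortality = MortalitySpec(
            background_annual_mortality={
                int(a): float(q)
                for a, q in _require(
                    supp, "background_annual_mortality", "supplementary_assumed"
                ).items()
            },
            ae_case_fatality=_class_map(supp, "ae_case_fatality", AE_CLASSES),
            post_state_excess_hazard_ratio={
                str(c): float(v)
                for c, v in _require(
                    supp, "post_state_excess_hazard_ratio", "supplementary_assumed"
                ).items()
            },
        )
        ppi = _require(t1, "ppi_rr", "paper_table1")
        pset = cls(
            economics=economics,
            risk_group=rg,
            costs=costs,
            utilities=utilities,
            mortality=mortality,
            diclofenac_absolute_rate=_class_map(
                t1, "diclofenac_absolute_rate", AE_CLASSES
            ),
            rr_celecoxib_vs_diclofenac=_class_map(
                t1, "rr_celecoxib_vs_diclofenac", AE_CLASSES
            ),
            rr_imrecoxib_vs_celecoxib=_class_map(
                t1, "rr_imrecoxib_vs_celecoxib", AE_CLASSES
            ),
            ppi_rr_traditional=_class_map(ppi, "traditional_nsaid", GI_CLASSES),
            ppi_rr_cox2=_class_map(ppi, "cox2_inhibitor", GI_CLASSES),
            withdrawal_fraction={
                str(k): float(v)
                for k, v in _require(design, "withdrawal_fraction", "design").items()
            },
            drug_cost_per_cycle={
                str(k): float(v)
                for k, v in _require(
                    supp, "drug_cost_per_cycle", "supplementary_assumed"
                ).items()
            },
        )
        pset.refresh_derived()
        pset.validate()
        return pset

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


def load_parameter_set(
    config_path: str | Path, risk_group: str | None = None
) -> ParameterSet:
    """Load, derive, and validate a :class:`ParameterSet` from a YAML file."""
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValidationError(f"{config_path}: config must be a mapping")
    return ParameterSet.from_config(config, risk_group=risk_group)


def default_parameter_set(risk_group: str = "low") -> ParameterSet:
    """The packaged base-case scenario for the given risk group."""
    return load_parameter_set(default_config_path(), risk_group=risk_group)


def default_config_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("oacea").joinpath("data/oa_base_case.yaml")))


# ---------------------------------------------------------------------------
# Parameter paths (used by DSA and PSA)
# ---------------------------------------------------------------------------

def get_path(pset: ParameterSet, path: str) -> float:
    """Resolve a dotted path (attributes and mapping keys) on a ParameterSet."""
    obj = pset
    for part in path.split("."):
        if isinstance(obj, Mapping):
            key: object = part
            if part not in obj:
                try:
                    key = int(part)
                except ValueError:
                    pass
            try:
                obj = obj[key]
            except KeyError:
                raise ValidationError(f"cannot resolve parameter path {path!r}")
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ValidationError(f"cannot resolve parameter path {path!r}")
    return obj


def set_path(pset: ParameterSet, path: str, value: float) -> None:
    """Set a dotted path on a ParameterSet in place (no re-derivation)."""
    parts = path.split(".")
    obj: object = pset
    for part in parts[:-1]:
        if isinstance(obj, Mapping):
            key: object = part
            if part not in obj:
                try:
                    key = int(part)
                except ValueError:
                    pass
            obj = obj[key]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ValidationError(f"cannot resolve parameter path {path!r}")
    leaf = parts[-1]
    if isinstance(obj, dict):
        key = leaf
        if leaf not in obj:
            try:
                key = int(leaf)
            except ValueError:
                pass
        if key not in obj:
            raise ValidationError(f"cannot resolve parameter path {path!r}")
        obj[key] = value
    elif hasattr(obj, leaf):
        setattr(obj, leaf, value)
    else:
        raise ValidationError(f"cannot resolve parameter path {path!r}")


def parameter_inventory(pset: ParameterSet) -> list[tuple[str, str]]:
    """Enumerate every scalar uncertain input as (path, kind).

    Kinds drive default sensitivity-analysis behaviour: ``cost`` (gamma in
    PSA), ``probability`` and ``utility`` (beta, clipped to [0,1] in DSA),
    ``rr`` (lognormal), ``discount`` (DSA range [0, 0.08], fixed in PSA).
    Derived quantities (indirect RRs, post-GI costs, resolved strategy
    fields) are excluded — perturb their primary inputs instead.
    """
    inv: list[tuple[str, str]] = []
    for c in AE_CLASSES:
        inv.append((f"costs.initial_state_cost.{c}", "cost"))
    for c in CV_CLASSES:
        inv.append((f"costs.post_state_cost.{c}", "cost"))
    inv.append(("costs.oa_management_cost_per_cycle", "cost"))
    inv.append(("costs.topical_diclofenac_cost_per_cycle", "cost"))
    for drug in sorted(pset.drug_cost_per_cycle):
        inv.append((f"drug_cost_per_cycle.{drug}", "cost"))
    for c in SEVERE_GI_CLASSES:
        inv.append((f"costs.recurrence_rate.{c}", "probability"))
    for c in AE_CLASSES:
        inv.append((f"utilities.weight_initial.{c}", "utility"))
        inv.append((f"utilities.weight_post.{c}", "utility"))
    inv.append(("utilities.baseline_on_treatment", "utility"))
    inv.append(("utilities.withdrawal_utility_decrement", "utility"))
    for c in AE_CLASSES:
        inv.append((f"diclofenac_absolute_rate.{c}", "probability"))
    for c in AE_CLASSES:
        inv.append((f"rr_celecoxib_vs_diclofenac.{c}", "rr"))
        inv.append((f"rr_imrecoxib_vs_celecoxib.{c}", "rr"))
    for c in GI_CLASSES:
        inv.append((f"ppi_rr_traditional.{c}", "rr"))
        inv.append((f"ppi_rr_cox2.{c}", "rr"))
    for k in ("traditional_nsaid", "cox2_inhibitor"):
        inv.append((f"withdrawal_fraction.{k}", "probability"))
    for c in AE_CLASSES:
        inv.append((f"mortality.ae_case_fatality.{c}", "probability"))
    inv.append(("economics.annual_discount_rate_cost", "discount"))
    inv.append(("economics.annual_discount_rate_qaly", "discount"))
    return inv


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require(mapping: Mapping, key: str, context: str = "config"):
    if key not in mapping:
        raise ValidationError(f"{context}.{key} is missing")
    return mapping[key]


def _require_classes(mapping: Mapping, context: str) -> None:
    for c in AE_CLASSES:
        if c not in mapping:
            raise ValidationError(f"{context}.{c} is missing")


def _class_map(
    mapping: Mapping, key: str, classes: Iterable[str]
) -> dict[str, float]:
    table = _require(mapping, key)
    out: dict[str, float] = {}
    for c in classes:
        if c not in table:
            raise ValidationError(f"{key}.{c} is missing")
        out[c] = float(table[c])
    return out
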