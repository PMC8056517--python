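"""Seeded generation of the model inputs that are not publicly tabulated.

The published evidence base of the model (event costs, utility weights,
absolute AE rates, relative risks) is fixed and never randomized here.
What this module generates are the *supplementary* inputs — background
mortality, AE case fatality, per-cycle drug and management costs, and
baseline utilities — as plausible, seeded values, so the full pipeline is
testable end to end without any external data.

Background mortality follows a Gompertz law, q(a) = 1 - exp(-A e^{B(a-55)}),
the standard two-parameter description of adult mortality: A is the annual
hazard at age 55 and B the log-hazard slope per year of age.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import params as P


def default_supplementary_block() -> dict:
    """The packaged, non-random ASSUMED defaults for every
    supplementary-sourced parameter (the ``supplementary_assumed`` block of
    the shipped base-case config)."""
    with open(P.default_config_path()) as fh:
        cfg = yaml.safe_load(fh)
    return copy.deepcopy(cfg["supplementary_assumed"])


def _default_case_fatality_ranges() -> dict[str, tuple[float, float]]:
    return {
        "gi_discomfort": (0.0, 0.0),
        "symptomatic_ulcer": (0.002, 0.01),
        "complicated_gi": (0.02, 0.08),
        "stroke": (0.10, 0.20),
        "mi": (0.08, 0.18),
        "hf": (0.05, 0.12),
    }


@dataclass
class FixtureConfig:
    """Ranges from which one synthetic supplementary block is drawn.

    All ranges are inclusive [low, high] intervals; a degenerate interval
    pins the value.  Defaults bracket the packaged assumed base case.
    """

    seed: int = 0
    #: Gompertz (hazard at age 55, log-hazard slope per year).
    mortality_level_range: tuple[float, float] = (0.003, 0.006)
    mortality_slope_range: tuple[float, float] = (0.07, 0.11)
    drug_cost_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "diclofenac": (5.0, 12.0),
            "imrecoxib": (14.0, 28.0),
            "omeprazole": (6.0, 14.0),
        }
    )
    oa_management_cost_range: tuple[float, float] = (1.0, 6.0)
    topical_cost_range: tuple[float, float] = (4.0, 9.0)
    on_treatment_utility_range: tuple[float, float] = (0.65, 0.80)
    withdrawn_utility_range: tuple[float, float] = (0.45, 0.62)
    case_fatality_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_case_fatality_ranges
    )
    post_excess_hazard_range: tuple[float, float] = (1.0, 1.0)

    def validate(self) -> None:
        for name, (lo, hi) in self._all_ranges():
            if lo > hi:
                raise P.ValidationError(
                    f"fixture range {name} is empty: ({lo}, {hi})"
                )
            if lo < 0:
                raise P.ValidationError(f"fixture range {name} negative")
        for name in ("diclofenac", "imrecoxib", "omeprazole"):
            if name not in self.drug_cost_ranges:
                raise P.ValidationError(f"drug_cost_ranges.{name} missing")
        for c in P.AE_CLASSES:
            if c not in self.case_fatality_ranges:
                raise P.ValidationError(f"case_fatality_ranges.{c} missing")
            if self.case_fatality_ranges[c][1] >= 1.0:
                raise P.ValidationError(
                    f"case_fatality_ranges.{c} must stay below 1"
                )
        for name in (
            "on_treatment_utility_range", "withdrawn_utility_range"
        ):
            if getattr(self, name)[1] > 1.0:
                raise P.ValidationError(f"{name} must stay within [0, 1]")
        if self.post_excess_hazard_range[0] < 1.0:
            raise P.ValidationError("post_excess_hazard_range must be >= 1")

    def _all_ranges(self):
        yield "mortality_level_range", self.mortality_level_range
        yield "mortality_slope_range", self.mortality_slope_range
        for k, v in self.drug_cost_ranges.items():
            yield f"drug_cost_ranges.{k}", v
        yield "oa_management_cost_range", self.oa_management_cost_range
        yield "topical_cost_range", self.topical_cost_range
        yield "on_treatment_utility_range", self.on_treatment_utility_range
        yield "withdrawn_utility_range", self.withdrawn_utility_range
        for k, v in self.case_fatality_ranges.items():
            yield f"case_fatality_ranges.{k}", v
        yield "post_excess_hazard_range", self.post_excess_hazard_range


def gompertz_mortality(
    level: float, slope: float, ages: range = range(55, 81)
) -> dict[int, float]:
    """Annual death probabilities from a Gompertz hazard anchored at 55."""
    return {
        a: 1.0 - math.exp(-level * math.exp(slope * (a - 55))) for a in ages
    }


def sample_supplementary_block(fixture: FixtureConfig) -> dict:
    """Draw one synthetic ``supplementary_assumed`` block."""
    fixture.validate()
    rng = np.random.default_rng(fixture.seed)

    def draw(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    level = draw(fixture.mortality_level_range)
    slope = draw(fixture.mortality_slope_range)
    u_on = draw(fixture.on_treatment_utility_range)
    u_wd = min(draw(fixture.withdrawn_utility_range), u_on)
    return {
        "drug_cost_per_cycle": {
            k: draw(v) for k, v in sorted(fixture.drug_cost_ranges.items())
        },
        "oa_management_cost_per_cycle": draw(fixture.oa_management_cost_range),
        "topical_diclofenac_cost_per_cycle": draw(fixture.topical_cost_range),
        "baseline_utility": {"on_treatment": u_on, "withdrawn": u_wd},
        "post_utility_baseline": "withdrawn",
        "ae_case_fatality": {
            c: draw(fixture.case_fatality_ranges[c]) for c in P.AE_CLASSES
        },
        "post_state_excess_hazard_ratio": {
            c: draw(fixture.post_excess_hazard_range)
            for c in P.AE_CLASSES
            if c != "gi_discomfort"
        },
        "background_annual_mortality": {
            a: round(q, 6) for a, q in gompertz_mortality(level, slope).items()
        },
    }


def generate_fixture_paramset(
    fixture: FixtureConfig, risk_group: str = "low"
) -> P.ParameterSet:
    """A complete, validated ParameterSet combining the published input
    values (never randomized) with one sampled supplementary block.
    Deterministic given the fixture seed."""
    with open(P.default_config_path()) as fh:
        cfg = yaml.safe_load(fh)
    cfg["supplementary_assumed"] = sample_supplementary_block(fixture)
    return P.ParameterSet.from_config(cfg, risk_group=risk_group)


def write_fixture_config(fixture: FixtureConfig, path) -> None:
    """Emit a complete params config with a sampled supplementary block."""
    with open(P.default_config_path()) as fh:
        cfg = yaml.safe_load(fh)
    cfg["supplementary_assumed"] = sample_supplementary_block(fixture)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
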