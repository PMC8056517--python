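"""One-way deterministic sensitivity analysis (tornado analysis).

Each uncertain scalar input is swept to its low and high value (by default
±20% of the base case, or the 0–8% guideline range for discount rates),
the whole pipeline is re-run, and the resulting ICERs for the target
comparisons are recorded.  Entries sorted by descending ICER spread form
the tornado diagram.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import params as P
from .cea import pairwise_icer
from .markov import evaluate_strategy

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("imrecoxib", "diclofenac"),
)


@dataclass
class DsaSpec:
    """One parameter sweep: path into the ParameterSet plus its range."""

    parameter_id: str
    low: float
    high: float
    target_comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS

    def validate(self, base: float) -> None:
        if not self.low <= base <= self.high:
            raise P.ValidationError(
                f"DSA range for {self.parameter_id} must bracket the base "
                f"value ({self.low} <= {base} <= {self.high} fails)"
            )


@dataclass
class TornadoEntry:
    parameter_id: str
    low: float
    high: float
    #: ICER of each target comparison at the low / high parameter value.
    icer_at_low: dict[tuple[str, str], float] = field(default_factory=dict)
    icer_at_high: dict[tuple[str, str], float] = field(default_factory=dict)
    spread: float = 0.0


def default_dsa_specs(
    pset: P.ParameterSet,
    relative_range: float = 0.20,
    target_comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
) -> list[DsaSpec]:
    """±20% sweeps for every scalar cost, utility, probability, RR and
    withdrawal/recurrence fraction, and the 0–8% range for both discount
    rates.  Perturbed utilities and probabilities are clipped to [0, 1]
    at evaluation time."""
    specs = []
    for path, kind in P.parameter_inventory(pset):
        base = P.get_path(pset, path)
        if kind == "discount":
            low, high = 0.0, 0.08
        else:
            low = base * (1.0 - relative_range)
            high = base * (1.0 + relative_range)
        specs.append(
            DsaSpec(
                parameter_id=path,
                low=min(low, base),
                high=max(high, base),
                target_comparisons=target_comparisons,
            )
        )
    return specs


_CLIP_KINDS = {"probability", "utility"}


def _evaluate_at(
    pset: P.ParameterSet,
    path: str,
    value: float,
    comparisons: tuple[tuple[str, str], ...],
) -> dict[tuple[str, str], float]:
    kind = dict(P.parameter_inventory(pset)).get(path)
    if kind in _CLIP_KINDS or kind == "discount":
        hi = 0.08 if kind == "discount" else 1.0
        clipped = min(max(value, 0.0), hi)
        if clipped != value:
            logger.info(
                "DSA: %s=%g clipped to %g to stay in its domain",
                path, value, clipped,
            )
            value = clipped
    trial = pset.copy()
    P.set_path(trial, path, value)
    trial.refresh_derived()
    trial.validate()
    needed = sorted({name for pair in comparisons for name in pair})
    results = {name: evaluate_strategy(trial, name) for name in needed}
    out: dict[tuple[str, str], float] = {}
    for interv, comp in comparisons:
        c = pairwise_icer(results[interv], results[comp])
        out[(interv, comp)] = c.icer if c.icer is not None else float("nan")
    return out


def one_way_dsa(
    pset: P.ParameterSet, specs: list[DsaSpec] | None = None
) -> list[TornadoEntry]:
    """Run every sweep and return tornado entries sorted by descending
    spread (ties broken by parameter_id, so the ordering is stable)."""
    if specs is None:
        specs = default_dsa_specs(pset)
    entries: list[TornadoEntry] = []
    for spec in specs:
        base = P.get_path(pset, spec.parameter_id)
        spec.validate(base)
        icer_low = _evaluate_at(
            pset, spec.parameter_id, spec.low, spec.target_comparisons
        )
        icer_high = _evaluate_at(
            pset, spec.parameter_id, spec.high, spec.target_comparisons
        )
        spread = max(
            (
                abs(icer_high[pair] - icer_low[pair])
                for pair in spec.target_comparisons
            ),
            default=0.0,
        )
        entries.append(
            TornadoEntry(
                parameter_id=spec.parameter_id,
                low=spec.low,
                high=spec.high,
                icer_at_low=icer_low,
                icer_at_high=icer_high,
                spread=spread,
            )
        )
    entries.sort(key=lambda e: (-e.spread, e.parameter_id))
    return entries


def tornado_frame(entries: list[TornadoEntry]):
    """Tornado entries as a long-format pandas DataFrame."""
    import pandas as pd

    rows = []
    for e in entries:
        for pair in e.icer_at_low:
            rows.append(
                {
                    "parameter": e.parameter_id,
                    "comparison": f"{pair[0]}_vs_{pair[1]}",
                    "low": e.low,
                    "high": e.high,
                    "icer_low": e.icer_at_low[pair],
                    "icer_high": e.icer_at_high[pair],
                    "spread": e.spread,
                }
            )
    return pd.DataFrame(rows)
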