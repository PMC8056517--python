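"""Decision outputs: pairwise ICERs, net monetary benefit, and the
cost-effectiveness frontier with strict and extended dominance.

ICERs are always computed from unrounded model outputs; rounding is left to
table rendering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .markov import StrategyResult

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class IcerComparison:
    """One pairwise incremental comparison.

    ``icer`` is numeric whenever the QALY difference is nonzero; ``flag``
    qualifies it: None for the ordinary north-east quadrant (costlier,
    more effective), 'dominant'/'dominated' for the unambiguous quadrants,
    'south_west' for cheaper-and-worse (where the numeric ICER must be
    read as a forgone-savings ratio), and 'undefined' for identical
    results.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    flag: str | None


def pairwise_icer(
    intervention: StrategyResult, comparator: StrategyResult
) -> IcerComparison:
    """Incremental cost-effectiveness of ``intervention`` over ``comparator``."""
    dc = intervention.cost - comparator.cost
    de = intervention.qalys - comparator.qalys
    flag: str | None = None
    icer: float | None = None
    if dc == 0.0 and de == 0.0:
        flag = UNDEFINED
    elif dc <= 0.0 and de >= 0.0:
        flag = DOMINANT
        if de != 0.0:
            icer = dc / de
    elif dc >= 0.0 and de <= 0.0:
        flag = DOMINATED
        if de != 0.0:
            icer = dc / de
    elif dc < 0.0 and de < 0.0:
        # Cheaper and worse: report the ratio but flag the quadrant.
        flag = "south_west"
        icer = dc / de
    else:
        icer = dc / de
    return IcerComparison(
        intervention=intervention.strategy_name,
        comparator=comparator.strategy_name,
        delta_cost=dc,
        delta_qalys=de,
        icer=icer,
        flag=flag,
    )


def net_monetary_benefit(result: StrategyResult, threshold: float) -> float:
    """NMB = threshold x QALYs - cost, in USD."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return threshold * result.qalys - result.cost


@dataclass
class FrontierSegment:
    strategy: str
    cost: float
    qalys: float
    #: ICER versus the previous frontier strategy (None for the cheapest).
    icer_vs_previous: float | None


@dataclass
class FrontierReport:
    """Efficient strategies in ascending cost order with sequential ICERs,
    plus each excluded strategy labelled by its dominance type."""

    frontier: list[FrontierSegment]
    excluded: dict[str, str]  # name -> 'strictly_dominated' | 'extendedly_dominated'


def efficiency_frontier(results: Sequence[StrategyResult]) -> FrontierReport:
    """Cost-effectiveness frontier by the standard sequential-ICER algorithm.

    Sort by ascending cost (ties by name); drop strategies weakly dominated
    by any other (no more QALYs for at least the same cost); then
    iteratively drop extendedly dominated strategies until sequential ICERs
    strictly increase.
    """
    if len(results) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    items = sorted(results, key=lambda r: (r.cost, r.strategy_name))
    for a, b in zip(items, items[1:]):
        if a.cost == b.cost and a.qalys == b.qalys:
            logger.info(
                "identical strategies %s and %s; tie broken by name",
                a.strategy_name, b.strategy_name,
            )

    excluded: dict[str, str] = {}
    alive: list[StrategyResult] = []
    for r in items:
        dominated = any(
            o is not r
            and o.cost <= r.cost
            and o.qalys >= r.qalys
            and (o.cost < r.cost or o.qalys > r.qalys or o.strategy_name < r.strategy_name)
            for o in items
        )
        if dominated:
            excluded[r.strategy_name] = "strictly_dominated"
        else:
            alive.append(r)

    # Extended dominance: remove any interior strategy whose incoming ICER
    # is not strictly below its outgoing ICER.
    changed = True
    while changed and len(alive) > 2:
        changed = False
        for i in range(1, len(alive) - 1):
            icer_in = _seq_icer(alive[i - 1], alive[i])
            icer_out = _seq_icer(alive[i], alive[i + 1])
            if icer_in >= icer_out:
                excluded[alive[i].strategy_name] = "extendedly_dominated"
                del alive[i]
                changed = True
                break

    segments = [
        FrontierSegment(
            strategy=r.strategy_name,
            cost=r.cost,
            qalys=r.qalys,
            icer_vs_previous=None if i == 0 else _seq_icer(alive[i - 1], r),
        )
        for i, r in enumerate(alive)
    ]
    return FrontierReport(frontier=segments, excluded=excluded)


def _seq_icer(cheaper: StrategyResult, costlier: StrategyResult) -> float:
    de = costlier.qalys - cheaper.qalys
    dc = costlier.cost - cheaper.cost
    if de <= 0.0:
        return float("inf")
    return dc / de


def standard_comparisons(
    results: dict[str, StrategyResult]
) -> list[IcerComparison]:
    """The standard head-to-head comparisons: each PPI add-on or drug switch
    versus its natural comparator."""
    pairs = [
        ("diclofenac_ppi", "diclofenac"),
        ("imrecoxib", "diclofenac"),
        ("imrecoxib_ppi", "diclofenac_ppi"),
        ("imrecoxib_ppi", "imrecoxib"),
    ]
    return [
        pairwise_icer(results[i], results[c])
        for i, c in pairs
        if i in results and c in results
    ]


def results_table(results: dict[str, StrategyResult]):
    """Table of per-strategy cost/QALYs plus the standard comparisons,
    as a pandas DataFrame."""
    import pandas as pd

    comps = {c.intervention: c for c in standard_comparisons(results)}
    rows = []
    for name, r in sorted(results.items(), key=lambda kv: kv[1].cost):
        comp = comps.get(name)
        rows.append(
            {
                "strategy": name,
                "cost": r.cost,
                "qalys": r.qalys,
                "icer": comp.icer if comp else None,
                "comparator": comp.comparator if comp else None,
            }
        )
    return pd.DataFrame(rows)
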