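"""Probabilistic sensitivity analysis.

Each draw replaces every uncertain input with a random value from its
assigned distribution (gamma for costs, beta for probabilities and
utilities, lognormal for relative risks, all parameterized by method of
moments from the base-case mean and a standard error defaulting to 20% of
the mean), re-derives the dependent quantities, and evaluates all four
strategies on the same sampled parameter set.  Outputs: per-draw
cost/QALY samples, head-to-head cost-effectiveness probabilities at a
willingness-to-pay threshold, and cost-effectiveness acceptability curves
(CEACs).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import params as P
from .markov import evaluate_all

logger = logging.getLogger(__name__)

DEFAULT_RELATIVE_SE = 0.20
#: Abort if more than this fraction of draws has to be resampled.
MAX_RESAMPLE_RATE = 0.01

_KIND_TO_FAMILY = {"cost": "gamma", "probability": "beta", "utility": "beta", "rr": "lognormal"}


@dataclass
class DistributionSpec:
    """Sampling distribution of one scalar parameter.

    ``mean`` is the base-case value; ``dispersion`` its standard error.
    The family must match the parameter's domain (gamma on [0, inf) for
    costs, beta on [0, 1] for probabilities/utilities, lognormal on
    (0, inf) for relative risks).
    """

    parameter_id: str
    family: str  # gamma | beta | lognormal
    mean: float
    dispersion: float

    def validate(self) -> None:
        if self.family not in ("gamma", "beta", "lognormal"):
            raise P.ValidationError(
                f"{self.parameter_id}: unknown family {self.family!r}"
            )
        if self.dispersion < 0:
            raise P.ValidationError(
                f"{self.parameter_id}: dispersion must be >= 0"
            )
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise P.ValidationError(
                f"{self.parameter_id}: beta mean must be in [0, 1], got {self.mean}"
            )
        if self.family in ("gamma", "lognormal") and self.mean < 0:
            raise P.ValidationError(
                f"{self.parameter_id}: mean must be >= 0, got {self.mean}"
            )

    def sample(self, rng: np.random.Generator) -> float:
        """One method-of-moments draw; degenerate cases return the mean."""
        m, s = self.mean, self.dispersion
        if s == 0.0 or m == 0.0:
            return m
        if self.family == "gamma":
            shape = (m / s) ** 2
            scale = s * s / m
            return float(rng.gamma(shape, scale))
        if self.family == "lognormal":
            sigma2 = math.log1p((s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return float(rng.lognormal(mu, math.sqrt(sigma2)))
        # beta: mean 1 (or 0) admits no spread; cap the SE so both shape
        # parameters stay positive.
        if m >= 1.0:
            return m
        s_max = math.sqrt(m * (1.0 - m))
        if s >= s_max:
            s = 0.95 * s_max
        nu = m * (1.0 - m) / (s * s) - 1.0
        if nu <= 0:
            raise P.ValidationError(
                f"{self.parameter_id}: infeasible beta moment match "
                f"(mean {m}, se {s})"
            )
        return float(rng.beta(m * nu, (1.0 - m) * nu))


def default_distribution_specs(
    pset: P.ParameterSet, relative_se: float = DEFAULT_RELATIVE_SE
) -> list[DistributionSpec]:
    """One spec per uncertain scalar input (discount rates stay fixed)."""
    specs: list[DistributionSpec] = []
    for path, kind in P.parameter_inventory(pset):
        if kind == "discount":
            continue
        mean = P.get_path(pset, path)
        specs.append(
            DistributionSpec(
                parameter_id=path,
                family=_KIND_TO_FAMILY[kind],
                mean=mean,
                dispersion=relative_se * mean,
            )
        )
    return specs


@dataclass
class PSASample:
    draw_index: int
    seed: int
    #: strategy name -> (discounted cost, discounted QALYs)
    results: dict[str, tuple[float, float]] = field(default_factory=dict)


def sample_parameter_set(
    base: P.ParameterSet,
    specs: Sequence[DistributionSpec],
    seed: int,
    draw_index: int,
) -> P.ParameterSet:
    """A valid ParameterSet with every listed parameter replaced by a draw.

    The RNG is seeded from (seed, draw_index), so any draw is reproducible
    in isolation and independent of evaluation order.  Derived quantities
    (indirect RRs, post-GI costs, strategy specs) are recomputed after
    sampling; sampled utility weights are reconciled with the
    initial-vs-post ordering by capping each initial weight at its post
    counterpart.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(draw_index)]))
    trial = base.copy()
    for spec in specs:
        spec.validate()
        P.set_path(trial, spec.parameter_id, spec.sample(rng))
    # Sampling initial and post utility weights independently can invert
    # their ordering; enforce initial <= post.
    for c in P.AE_CLASSES:
        wi = trial.utilities.weight_initial[c]
        wp = trial.utilities.weight_post[c]
        if wi > wp:
            trial.utilities.weight_initial[c] = wp
    trial.refresh_derived()
    trial.validate()
    return trial


def run_psa(
    base: P.ParameterSet,
    specs: Sequence[DistributionSpec] | None = None,
    n_draws: int = 5000,
    seed: int = 0,
) -> list[PSASample]:
    """Monte-Carlo evaluation: ``n_draws`` sampled parameter sets, each
    with all four strategies evaluated on the same draw.

    Draws whose sampled parameters produce an unbuildable model are
    resampled (with a fresh sub-seed) and counted; a resample rate above
    1% aborts the analysis.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if specs is None:
        specs = default_distribution_specs(base)
    samples: list[PSASample] = []
    n_resampled = 0
    for i in range(n_draws):
        attempt = i
        while True:
            try:
                trial = sample_parameter_set(base, specs, seed, attempt)
                results = evaluate_all(trial)
                break
            except (P.ValidationError, ValueError) as exc:
                n_resampled += 1
                if n_resampled > max(1, MAX_RESAMPLE_RATE * n_draws):
                    raise RuntimeError(
                        f"PSA resample rate exceeded {MAX_RESAMPLE_RATE:.0%} "
                        f"({n_resampled} invalid draws); last error: {exc}"
                    ) from exc
                logger.warning("PSA draw %d invalid (%s); resampling", i, exc)
                # Deterministic fallback sub-seed outside the normal range.
                attempt = n_draws + n_resampled * (n_draws + 1) + i
        samples.append(
            PSASample(
                draw_index=i,
                seed=seed,
                results={
                    name: (r.mean_discounted_cost, r.mean_discounted_qalys)
                    for name, r in results.items()
                },
            )
        )
    if n_resampled:
        logger.info("PSA: %d draws resampled", n_resampled)
    return samples


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _nmb(sample: PSASample, strategy: str, threshold: float) -> float:
    cost, qalys = sample.results[strategy]
    return threshold * qalys - cost


def ce_probability(
    samples: Sequence[PSASample],
    intervention: str,
    comparator: str,
    threshold: float,
) -> float:
    """Fraction of draws in which the intervention's net monetary benefit
    exceeds the comparator's at the given threshold (ties count 0.5)."""
    if not samples:
        raise ValueError("no PSA samples")
    wins = 0.0
    for s in samples:
        a = _nmb(s, intervention, threshold)
        b = _nmb(s, comparator, threshold)
        if a > b:
            wins += 1.0
        elif a == b:
            wins += 0.5
    return wins / len(samples)


def strict_dominance_probability(
    samples: Sequence[PSASample], intervention: str, comparator: str
) -> float:
    """Fraction of draws in which the intervention is cheaper and more
    effective than the comparator (per-draw strict dominance)."""
    if not samples:
        raise ValueError("no PSA samples")
    wins = sum(
        1
        for s in samples
        if s.results[intervention][0] < s.results[comparator][0]
        and s.results[intervention][1] > s.results[comparator][1]
    )
    return wins / len(samples)


@dataclass
class CeacTable:
    thresholds: np.ndarray  # (T,)
    strategies: list[str]
    #: (T, n_strategies) probability each strategy is most cost-effective.
    probabilities: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probabilities, columns=self.strategies)
        df.insert(0, "threshold", self.thresholds)
        return df

    def most_probable(self) -> list[str]:
        """Modal strategy at each threshold."""
        idx = np.argmax(self.probabilities, axis=1)
        return [self.strategies[i] for i in idx]


def ceac(
    samples: Sequence[PSASample],
    strategies: Sequence[str] | None = None,
    threshold_grid: Sequence[float] | None = None,
) -> CeacTable:
    """Cost-effectiveness acceptability curves.

    For each threshold, the fraction of draws in which each strategy
    attains the maximum NMB; exact ties split their draw equally.
    """
    if not samples:
        raise ValueError("no PSA samples")
    if strategies is None:
        strategies = sorted(samples[0].results)
    grid = np.asarray(
        threshold_grid if threshold_grid is not None else P.default_threshold_grid(),
        dtype=float,
    )
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be nonempty and ascending")
    costs = np.array([[s.results[name][0] for name in strategies] for s in samples])
    qalys = np.array([[s.results[name][1] for name in strategies] for s in samples])
    probs = np.zeros((grid.size, len(strategies)))
    for t, lam in enumerate(grid):
        nmb = lam * qalys - costs  # (draws, strategies)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[t] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacTable(
        thresholds=grid, strategies=list(strategies), probabilities=probs
    )


def scatter_frame(
    samples: Sequence[PSASample], intervention: str, comparator: str
):
    """Incremental cost/QALY cloud (one row per draw) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "draw": s.draw_index,
            "delta_cost": s.results[intervention][0] - s.results[comparator][0],
            "delta_qalys": s.results[intervention][1] - s.results[comparator][1],
        }
        for s in samples
    ]
    return pd.DataFrame(rows)


def samples_frame(samples: Sequence[PSASample]):
    """All PSA samples in long format (draw, strategy, cost, qalys)."""
    import pandas as pd

    rows = [
        {"draw": s.draw_index, "strategy": name, "cost": c, "qalys": q}
        for s in samples
        for name, (c, q) in sorted(s.results.items())
    ]
    return pd.DataFrame(rows)
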