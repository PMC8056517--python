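# oacea — cost-utility analysis of NSAID strategies for osteoarthritis

`oacea` is a Markov cohort cost-utility model comparing four long-term
pain-management strategies for osteoarthritis from a Chinese healthcare
perspective: **diclofenac** (a traditional NSAID), **imrecoxib** (a
selective COX-2 inhibitor), and each drug co-prescribed with a
proton-pump inhibitor (omeprazole).  It is written for health economists
and modellers who want a tested, scriptable implementation of the
NICE-style osteoarthritis adverse-event model: the same engine drives the
deterministic base case, one-way (tornado) sensitivity analysis, and a
full probabilistic sensitivity analysis with cost-effectiveness
acceptability curves.

## The model

A cohort enters at age 55 (low GI/CV risk) or 65 (high risk: 2.96× the
ulcer/complicated-GI hazard and 1.94× the cardiovascular hazard) and is
followed in 3-month cycles until age 80 over 14 health states: well on
treatment; six acute adverse-event states (GI discomfort, symptomatic
ulcer, complicated GI, stroke, MI, heart failure); five lifelong post-event
states; withdrawal to topical diclofenac; and death.  Strategy differences
enter through relative risks on the diclofenac event rates, composed on the
hazard scale:

    r = −ln(1 − P₁)/t₁,   P₂ = 1 − exp(−r·RR·t₂)

The imrecoxib-vs-diclofenac relative risks are obtained by indirect
comparison through celecoxib (RR_AC = RR_AB × RR_BC).  Costs (2019 USD,
CPI-chained and converted at 6.8985 RMB/USD) and utilities are accrued per
cycle with a trapezoid half-cycle correction and discounted at 5%/year:

    E[X] = Σₖ (occₖ + occₖ₊₁)/2 · v · (1+d)^(−0.25k)

Decision outputs are incremental cost-effectiveness ratios
(ICER = ΔC/ΔE), the dominance/extended-dominance frontier, net monetary
benefit (NMB = λ·E − C), and, over Monte-Carlo parameter draws (gamma
costs, beta probabilities/utilities, lognormal relative risks; method of
moments, SE = 20% of the mean), cost-effectiveness acceptability curves.

Published input values ship in `src/oacea/data/oa_base_case.yaml` under
`paper_table1`; inputs that the source analysis drew from non-public
supplementary tables (drug prices, background mortality, case fatality,
baseline utilities) are clearly partitioned under `supplementary_assumed`
and are documented, plausible stand-ins — see `docs/methods.md` for how
they were chosen and what that means for interpreting results.

## Worked example

```python
from oacea import default_parameter_set, evaluate_all
from oacea.cea import results_table, efficiency_frontier

pset = default_parameter_set("low")          # 55-year-old, low-risk cohort
results = evaluate_all(pset)
print(results_table(results).to_string(index=False))
```

```
      strategy        cost    qalys        icer comparator
    diclofenac 1021.636056 8.893751         NaN       None
diclofenac_ppi 1604.966631 9.233670 1716.086229 diclofenac
     imrecoxib 1848.647642 9.331310 1890.056229 diclofenac
 imrecoxib_ppi 2494.344153 9.503440 3751.217237  imrecoxib
```

Read: per patient over the 25-year horizon, diclofenac alone is cheapest
($1,022) but yields the fewest QALYs (8.89), mostly because GI discomfort
drives many patients off the oral drug onto less effective topical
treatment.  Adding omeprazole to diclofenac buys QALYs at $1,716 each;
switching to imrecoxib costs $1,890 per QALY gained over diclofenac — far
below the ≈$10,000 (1× Chinese GDP per capita) benchmark.  No strategy is
dominated: `efficiency_frontier(list(results.values()))` keeps all four,
with sequential ICERs rising from $1,716 to $3,751 per QALY.

The same analyses from the shell:

```sh
oacea cea --risk-group low --out results/
oacea dsa --risk-group low --out results/           # tornado table
oacea psa --risk-group low --n-draws 5000 --seed 1 --out results/
oacea make-fixtures --seed 7 --out my_params.yaml   # synthetic config
```

All commands accept `--params FILE` to run a modified configuration.

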