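# Base-case parameter configuration for the osteoarthritis NSAID/COX-2
# cost-utility model.
#
# Provenance is partitioned by top-level block:
#   design                — study design constants (cohort, discounting,
#                           withdrawal fractions) from the published analysis.
#   paper_table1          — published input values (costs in 2019 USD,
#                           utility weights, absolute AE rates, relative
#                           risks).  Never altered by fixture generation.
#   supplementary_assumed — values the publication sourced from supplementary
#                           tables that are not publicly printed.  Every
#                           entry here is ASSUMED: a plausible, documented
#                           stand-in calibrated so the base case reproduces
#                           the published qualitative structure.  Replace
#                           with the true values if you have them.

design:
  economics:
    annual_discount_rate_cost: 0.05    # Chinese pharmacoeconomic guideline
    annual_discount_rate_qaly: 0.05
    cycle_length_years: 0.25           # 3-month cycles
    # Observation period (years) of the absolute AE probabilities below:
    # 1.0 treats them as annualized (their sources are annualized trial
    # meta-reviews); 0.25 would apply them per cycle.
    absolute_rate_observation_years: 1.0
    threshold_grid: null               # null -> default 0..30000 USD/QALY grid
  risk_groups:
    # Horizon runs to age 80 in both groups.
    low:  {start_age: 55, n_cycles: 100, gi_risk_multiplier: 1.0,  cv_risk_multiplier: 1.0}
    high: {start_age: 65, n_cycles: 60,  gi_risk_multiplier: 2.96, cv_risk_multiplier: 1.94}
  # Fraction of GI-discomfort patients who stop the oral drug per occurrence.
  withdrawal_fraction:
    traditional_nsaid: 0.139
    cox2_inhibitor: 0.112

paper_table1:
  # Per-event-cycle cost of each acute AE state, 2019 USD.  The GI-discomfort
  # entry is the add-on outpatient cost; routine OA management and drug costs
  # are accrued separately for that state.
  initial_state_cost:
    gi_discomfort: 10.52
    symptomatic_ulcer: 34.57
    complicated_gi: 1354.15
    stroke: 1289.92
    mi: 5190.93
    hf: 1182.33
  # Per-cycle maintenance cost of the post-CV states (post-GI maintenance
  # costs are derived as initial cost x recurrence rate).
  post_state_cost_cv:
    stroke: 619.59
    mi: 948.47
    hf: 451.29
  # Per-cycle recurrence probability of severe GI events.
  recurrence_rate:
    symptomatic_ulcer: 0.0233
    complicated_gi: 0.0159
  # Utility weights, 1 = OA patient on treatment with no AE.
  utility_weight_initial:
    gi_discomfort: 0.73
    symptomatic_ulcer: 0.55
    complicated_gi: 0.46
    stroke: 0.35
    mi: 0.37
    hf: 0.71
  utility_weight_post:
    gi_discomfort: 1.00
    symptomatic_ulcer: 0.98
    complicated_gi: 0.98
    stroke: 0.71
    mi: 0.88
    hf: 1.00
  # Absolute AE probabilities on diclofenac (pooled trial evidence),
  # observed over design.economics.absolute_rate_observation_years.
  diclofenac_absolute_rate:
    gi_discomfort: 0.2130
    symptomatic_ulcer: 0.0014
    complicated_gi: 0.0007
    stroke: 0.0006
    mi: 0.0009
    hf: 0.0002
  # Component relative risks; the imrecoxib-vs-diclofenac row is derived by
  # indirect comparison (product of the two rows below).
  rr_celecoxib_vs_diclofenac:
    gi_discomfort: 0.66
    symptomatic_ulcer: 0.43
    complicated_gi: 0.68
    stroke: 0.51
    mi: 1.40
    hf: 1.42
  rr_imrecoxib_vs_celecoxib:
    gi_discomfort: 0.50
    symptomatic_ulcer: 1.36
    complicated_gi: 0.50
    stroke: 1.00
    mi: 1.00
    hf: 1.00
  # PPI (omeprazole) relative risks on the GI classes (CV classes unaffected).
  ppi_rr:
    traditional_nsaid:
      gi_discomfort: 0.43
      symptomatic_ulcer: 0.37
      complicated_gi: 0.46
    cox2_inhibitor:
      gi_discomfort: 0.25
      symptomatic_ulcer: 0.25
      complicated_gi: 0.25

supplementary_assumed:
  # ASSUMED per-cycle (3-month) drug acquisition costs, 2019 USD, at the
  # recommended doses (diclofenac 50 mg TID, imrecoxib 100 mg BID,
  # omeprazole 20 mg QD), Chinese generic/list prices.
  drug_cost_per_cycle:
    diclofenac: 8.0
    imrecoxib: 21.0
    omeprazole: 11.0
  # ASSUMED per-cycle outpatient OA management cost excluding drugs
  # (roughly one routine review visit per year).
  oa_management_cost_per_cycle: 2.0
  # ASSUMED per-cycle cost of topical diclofenac, the fallback after the
  # oral drug is stopped.
  topical_diclofenac_cost_per_cycle: 6.0
  # ASSUMED absolute utilities anchoring the Table-1 weights: on the oral
  # drug with no AE, and after withdrawal to topical diclofenac.
  baseline_utility:
    on_treatment: 0.72
    withdrawn: 0.55
  # Which baseline multiplies the post-state utility weights.
  post_utility_baseline: withdrawn
  # ASSUMED probability of dying from an acute AE during its event cycle.
  ae_case_fatality:
    gi_discomfort: 0.0
    symptomatic_ulcer: 0.005
    complicated_gi: 0.05
    stroke: 0.15
    mi: 0.12
    hf: 0.08
  # Hazard ratio on background mortality while in a post-AE state
  # (1 = no excess mortality beyond the general population).
  post_state_excess_hazard_ratio:
    symptomatic_ulcer: 1.0
    complicated_gi: 1.0
    stroke: 1.0
    mi: 1.0
    hf: 1.0
  # ASSUMED annual background mortality of the general population,
  # Gompertz hazard 0.004 * exp(0.09 * (age - 55)).
  background_annual_mortality:
    55: 0.00399
    56: 0.00437
    57: 0.00478
    58: 0.00523
    59: 0.00572
    60: 0.00625
    61: 0.00684
    62: 0.00748
    63: 0.00818
    64: 0.00895
    65: 0.00979
    66: 0.01071
    67: 0.01171
    68: 0.01281
    69: 0.01400
    70: 0.01531
    71: 0.01674
    72: 0.01830
    73: 0.02001
    74: 0.02187
    75: 0.02391
    76: 0.02613
    77: 0.02856
    78: 0.03120
    79: 0.03409
    80: 0.03724
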