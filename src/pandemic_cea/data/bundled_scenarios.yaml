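# Bundled calibrated scenarios, v1.
#
# Six pandemic-exacerbated conditions with their published per-million-adult
# summary values (2020 USD). Per-episode parameters and baseline prevalences
# are NOT transcribed from any source: they are back-solved at load time so
# that the forward model reproduces every printed cell (see
# pandemic_cea.calibration). All monetary values in USD; QALY cells in QALYs;
# burden and intervention cells are per one million adults.
#
# Fields per condition:
#   rr / rr_range        relative risk during the pandemic and its 95% range
#   cost_per_episode     total undiscounted (short + long) societal cost per episode
#   excess_qalys_*       excess QALYs lost (long-term cell already discounted)
#   excess_cost_*        excess societal costs (long-term cell already discounted)
#   qalys_gained         intervention lifetime QALYs gained
#   intervention_cost    total year-one intervention cost
#   net_savings_*        net savings at the 1/3/10-year horizons
#   severity_multiplier  scaling of health outcomes (homelessness: literature
#                        values reduced 75% for acute pandemic-related episodes)
#   coverage             fraction of affected adults reached (stroke: 100% of
#                        the at-risk pool)
#   rounding_unit        resolution the printed monetary cells were rounded to,
#                        used to set absolute tolerances on net-savings targets
version: 1
n_adults: 1000000
discount_rate: 0.03
long_term_lag_years: 10
conditions:
  depression:
    label: "Depressive symptoms"
    intervention_label: "Cognitive-behavioral therapy + antidepressants"
    rr: 1.37
    rr_range: [1.20, 2.56]
    cost_per_episode: 32599
    excess_qalys_short: 24831
    excess_qalys_long: 43807
    excess_cost_short: 954000000
    excess_cost_long: 1277000000
    qalys_gained: 12707
    intervention_cost: 44500000
    net_savings_year1: 61500000
    net_savings_year3: 161700000
    net_savings_year10: 241500000
    severity_multiplier: 1.0
    coverage: 0.20
    rounding_unit: 100000
  ipv:
    label: "Intimate partner violence"
    intervention_label: "Nurse-family partnership"
    rr: 1.11
    rr_range: [1.05, 1.16]
    cost_per_episode: 115562
    excess_qalys_short: 2445
    excess_qalys_long: 49902
    excess_cost_short: 373000000
    excess_cost_long: 326000000
    qalys_gained: 22186
    intervention_cost: 164700000
    net_savings_year1: -69800000
    net_savings_year3: 5300000
    net_savings_year10: 54600000
    severity_multiplier: 1.0
    coverage: 0.20
    rounding_unit: 100000
  homelessness:
    label: "Homelessness"
    intervention_label: "Rent subsidies"
    rr: 6.67
    rr_range: [5.34, 8.00]
    cost_per_episode: 99969
    excess_qalys_short: 12951
    excess_qalys_long: 3527
    excess_cost_short: 706000000
    excess_cost_long: 1448000000
    qalys_gained: 1648
    intervention_cost: 47100000
    net_savings_year1: -4700000
    net_savings_year3: 45400000
    net_savings_year10: 92400000
    severity_multiplier: 0.25
    coverage: 0.20
    rounding_unit: 100000
  alcohol:
    label: "Excessive alcohol use"
    intervention_label: "Screening and brief intervention"
    rr: 1.19
    rr_range: [1.07, 1.42]
    cost_per_episode: 94004
    excess_qalys_short: 5928
    excess_qalys_long: 19807
    excess_cost_short: 138000000
    excess_cost_long: 952000000
    qalys_gained: 4835
    intervention_cost: 6600000
    net_savings_year1: 8900000
    net_savings_year3: 52500000
    net_savings_year10: 107400000
    severity_multiplier: 1.0
    coverage: 0.20
    rounding_unit: 100000
  oud:
    label: "Opioid use disorder"
    intervention_label: "Medication-assisted treatment"
    rr: 1.63
    rr_range: [1.33, 1.98]
    cost_per_episode: 79551
    excess_qalys_short: 3239
    excess_qalys_long: 24877
    excess_cost_short: 166000000
    excess_cost_long: 385000000
    qalys_gained: 5674
    intervention_cost: 56200000
    net_savings_year1: -36000000
    net_savings_year3: -10500000
    net_savings_year10: 14500000
    severity_multiplier: 1.0
    coverage: 0.20
    rounding_unit: 100000
  stroke:
    label: "Stroke mortality"
    intervention_label: "Public awareness campaign"
    rr: 1.53
    rr_range: [1.40, 1.67]
    cost_per_episode: 16773
    excess_qalys_short: 1214
    excess_qalys_long: null
    excess_cost_short: 844000
    excess_cost_long: null
    qalys_gained: 388
    intervention_cost: 14350
    net_savings_year1: 147500
    net_savings_year3: 228500
    net_savings_year10: 242000
    severity_multiplier: 1.0
    coverage: 1.0
    rounding_unit: 500
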