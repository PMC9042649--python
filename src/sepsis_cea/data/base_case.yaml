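cohort:
  incidence: 0.141
  mean_age: 60.0
  n_icu_admissions_total: 45000
  n_icu_admissions_no_sepsis: 36900
algorithm_test:
  sensitivity: 0.8
  specificity: 0.851
comparator_test:
  sensitivity: 0.792
  specificity: 0.785
timing:
  t_tp: -3.0
  t_fn: 3.0
  t_antibiotic_from_detection: 0.0
shock_risk:
  p_ref: 0.566
  p_early: 0.4
  t_early: -3.0
  time_dependent: true
mortality:
  a: 0.4281
  b: 0.0272
  c: 0.0052
  rr_shock_multiplier: 1.0
  rr_noshock_multiplier: 1.0
  variant: fitted
  linear_anchor: 0.4
  linear_slope: 0.076
  constant_shock: 0.33
  constant_nonshock: 0.22
los:
  icu_shock: 7.4
  icu_noshock: 2.0
  icu_true_negative: 1.0
  icu_false_positive: 2.0
  ward_shock: 17.0
  ward_noshock: 5.7
  ward_true_negative: 5.7
  ward_false_positive: 5.7
costs:
  icu_day: 6355.38
  ward_day: 626.26
  readmission_event: 4166.0
  prediction_cost_per_patient: 1037.0
  prediction_price_per_icu_day: 90.0
  longterm_cost_per_survivor: 1947.73
postdischarge:
  readmission_rate_year1: 0.206
  postdischarge_mortality_year1_shock: 0.175
longterm:
  rr_years_1_5: 5.5
  rr_years_6_10: 3.1
  rr_years_11_plus: 1.0
  utility_decrement_years_1_5: -0.164
  utility_decrement_years_6_10: -0.124
  utility_decrement_years_11_plus: 0.0
  baseline_utility: 0.8
  discount_rate: 0.03
  consequence_frequencies:
    impaired_kidney_function: 0.141
    amputation: 0.085
    depression: 0.028
    ptsd: 0.099
  include_longterm_consequences: true
  time_horizon_years: null
  max_age: 105
psa_specs:
- parameter_name: incidence
  family: beta
  mean: 0.141
  se: 0.0038
- parameter_name: sensitivity_algorithm
  family: beta
  mean: 0.8
  se: 0.0183
- parameter_name: specificity_algorithm
  family: beta
  mean: 0.851
  se: 0.0068
- parameter_name: sensitivity_comparator
  family: beta
  mean: 0.792
  se: 0.0181
- parameter_name: specificity_comparator
  family: beta
  mean: 0.785
  se: 0.0063
- parameter_name: hours_to_treatment_tp
  family: normal
  mean: -3.0
  se: 0.5
- parameter_name: hours_to_treatment_fn
  family: normal
  mean: 3.0
  se: 0.5
- parameter_name: hours_to_antibiotic
  family: normal
  mean: 0.0
  se: 0.5
- parameter_name: shock_probability_early
  family: beta
  mean: 0.4
  se: 0.04
- parameter_name: shock_probability_soc
  family: beta
  mean: 0.566
  se: 0.0091
- parameter_name: rr_mortality_shock
  family: lognormal
  mean: 1.0
  se: 0.255
- parameter_name: rr_mortality_nonshock
  family: lognormal
  mean: 1.0
  se: 0.588
- parameter_name: hr_years_1_5_under60
  family: lognormal
  mean: 17.8
  se: 2.653
- parameter_name: hr_years_6_10_under60
  family: lognormal
  mean: 6.0
  se: 1.301
- parameter_name: hr_years_1_5_60to70
  family: lognormal
  mean: 5.5
  se: 1.25
- parameter_name: hr_years_6_10_60to70
  family: lognormal
  mean: 3.1
  se: 0.791
- parameter_name: hr_years_1_5_over70
  family: lognormal
  mean: 2.4
  se: 0.791
- parameter_name: hr_years_6_10_over70
  family: lognormal
  mean: 1.8
  se: 1.684
- parameter_name: icu_days_shock
  family: gamma
  mean: 7.4
  se: 0.1989
- parameter_name: icu_days_noshock
  family: gamma
  mean: 2.0
  se: 0.165
- parameter_name: icu_days_true_negative
  family: gamma
  mean: 1.0
  se: 0.0264
- parameter_name: icu_days_false_positive
  family: gamma
  mean: 2.0
  se: 0.0264
- parameter_name: ward_days_shock
  family: gamma
  mean: 17.0
  se: 0.457
- parameter_name: ward_days_noshock
  family: gamma
  mean: 5.7
  se: 0.4703
- parameter_name: ward_days_true_negative
  family: gamma
  mean: 5.7
  se: 0.1505
- parameter_name: ward_days_false_positive
  family: gamma
  mean: 5.7
  se: 0.1505
- parameter_name: postdischarge_mortality_shock
  family: beta
  mean: 0.175
  se: 0.0175
- parameter_name: readmission_rate
  family: beta
  mean: 0.206
  se: 0.0042
- parameter_name: utility_decrement_years_1_5
  family: normal
  mean: -0.164
  se: 0.0395
- parameter_name: utility_decrement_years_6_10
  family: normal
  mean: -0.124
  se: 0.0394
- parameter_name: utility_decrement_years_11_plus
  family: normal
  mean: 0.0
  se: 0.0
- parameter_name: freq_impaired_kidney_function
  family: beta
  mean: 0.141
  se: 0.0044
- parameter_name: freq_amputation
  family: beta
  mean: 0.085
  se: 0.0035
- parameter_name: freq_depression
  family: beta
  mean: 0.028
  se: 0.0021
- parameter_name: freq_ptsd
  family: beta
  mean: 0.099
  se: 0.0038
wtp_thresholds:
- 20000.0
- 50000.0
readmission_population: all_survivors
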