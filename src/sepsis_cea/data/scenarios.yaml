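- name: Incidence 30%
  overrides:
    cohort.incidence: 0.3
- name: Incidence 20%
  overrides:
    cohort.incidence: 0.2
- name: Incidence 10%
  overrides:
    cohort.incidence: 0.1
- name: 'Comparator sensitivity and specificity: SOFA (80.0% / 48.0%)'
  overrides:
    comparator_test.sensitivity: 0.8
    comparator_test.specificity: 0.48
- name: 'Comparator sensitivity and specificity: NEWS2 (84.0% / 37.0%)'
  overrides:
    comparator_test.sensitivity: 0.84
    comparator_test.specificity: 0.37
- name: Algorithm specificity 78.5% (Sepsis-3)
  overrides:
    algorithm_test.specificity: 0.785
- name: Detection 4 hours earlier
  overrides:
    timing.t_tp: -4.0
- name: Detection 2 hours earlier
  overrides:
    timing.t_tp: -2.0
- name: Detection 1 hour earlier
  overrides:
    timing.t_tp: -1.0
- name: Proportion septic shock 30% at earlier detection
  overrides:
    shock_risk.p_early: 0.3
- name: Proportion septic shock constant 56.6%
  overrides:
    shock_risk.time_dependent: false
- name: 'In-hospital mortality: linear survival decrease 7.6%/hour'
  overrides:
    mortality.variant: linear_survival
- name: 'In-hospital mortality constant: 33% shock / 22% no shock'
  overrides:
    mortality.variant: constant
- name: Length of stay ICU and ward +25%
  overrides:
    los.icu_shock:
      multiply: 1.25
    los.icu_noshock:
      multiply: 1.25
    los.icu_true_negative:
      multiply: 1.25
    los.icu_false_positive:
      multiply: 1.25
    los.ward_shock:
      multiply: 1.25
    los.ward_noshock:
      multiply: 1.25
    los.ward_true_negative:
      multiply: 1.25
    los.ward_false_positive:
      multiply: 1.25
- name: Length of stay ICU and ward -25%
  overrides:
    los.icu_shock:
      multiply: 0.75
    los.icu_noshock:
      multiply: 0.75
    los.icu_true_negative:
      multiply: 0.75
    los.icu_false_positive:
      multiply: 0.75
    los.ward_shock:
      multiply: 0.75
    los.ward_noshock:
      multiply: 0.75
    los.ward_true_negative:
      multiply: 0.75
    los.ward_false_positive:
      multiply: 0.75
- name: Septic shock postdischarge mortality first year 0%
  overrides:
    postdischarge.postdischarge_mortality_year1_shock: 0.0
- name: Readmission rate 0%
  overrides:
    postdischarge.readmission_rate_year1: 0.0
- name: Readmission rate 40%
  overrides:
    postdischarge.readmission_rate_year1: 0.4
- name: Unit cost of ICU and ward day +25%
  overrides:
    costs.icu_day:
      multiply: 1.25
    costs.ward_day:
      multiply: 1.25
- name: Unit cost of ICU and ward day -25%
  overrides:
    costs.icu_day:
      multiply: 0.75
    costs.ward_day:
      multiply: 0.75
- name: Unit cost of readmission +25%
  overrides:
    costs.readmission_event:
      multiply: 1.25
- name: Unit cost of readmission -25%
  overrides:
    costs.readmission_event:
      multiply: 0.75
- name: Long-term survival same as general population
  overrides:
    longterm.rr_years_1_5: 1.0
    longterm.rr_years_6_10: 1.0
    longterm.rr_years_11_plus: 1.0
- name: Long-term consequences not included
  overrides:
    longterm.include_longterm_consequences: false
- name: Model time horizon 1 year
  overrides:
    longterm.time_horizon_years: 1
- name: Discount rate 0%
  overrides:
    longterm.discount_rate: 0.0
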