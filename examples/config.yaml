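# Canonical configuration example.
#
# Every section is optional: anything omitted falls back to the built-in
# published defaults (and the fallback is logged).  Shown here with all
# default values written out, plus one custom cohort and scenario as
# illustration of overrides.

transitions:
  "NYHA II or III":
    p_hosp_by_state: {H0: 0.008, H1: 0.052, H2: 0.106, H3: 0.121, H4plus: 0.180}
    p_death_not_hospitalized: 0.007
    p_death_hospitalized: 0.100
  "NYHA III or IV":
    p_hosp_by_state: {H0: 0.008, H1: 0.168, H2: 0.213, H3: 0.268, H4plus: 0.334}
    p_death_not_hospitalized: 0.010
    p_death_hospitalized: 0.100

scenarios:
  best:  {sensitivity: 0.90, specificity: 0.90, mortality_reduction: 0.29,
          hospitalization_reduction: 0.38, los_reduction: 0.30}
  base:  {sensitivity: 0.80, specificity: 0.80, mortality_reduction: 0.24,
          hospitalization_reduction: 0.28, los_reduction: 0.25}
  worst: {sensitivity: 0.70, specificity: 0.70, mortality_reduction: 0.19,
          hospitalization_reduction: 0.18, los_reduction: 0.20}
  # a custom scenario: a cheap coaching-only program with a weaker test
  coaching: {sensitivity: 0.60, specificity: 0.85, mortality_reduction: 0.10,
             hospitalization_reduction: 0.12, los_reduction: 0.10}

costs:
  cost_per_admission: 12000      # USD per CHF hospitalization
  annual_chf_outpatient: 1700    # USD per alive patient-year
  annual_non_chf: 10000          # USD per alive patient-year
  monthly_install: 15            # telehealth, USD per patient-month
  monthly_monitoring: 80
  monthly_case_manager: 125
  treat_physician: 52            # USD per detected episode
  treat_nurse_visit: 135
  annual_discount_rate: 0.03

cohorts:
  C1: {initial_distribution: {H0: 1.0}, horizon_months: 60,
       nyha_label: "NYHA II or III"}
  C2: {initial_distribution: {H1: 0.30, H2: 0.30, H3: 0.40}, horizon_months: 60,
       nyha_label: "NYHA II or III"}
  C3: {initial_distribution: {H4plus: 1.0}, horizon_months: 60,
       nyha_label: "NYHA II or III"}
  # a severe-stratum cohort using the other hazard column
  C2_severe: {initial_distribution: {H1: 0.30, H2: 0.30, H3: 0.40},
              horizon_months: 60, nyha_label: "NYHA III or IV"}

options:
  detection_gated_reductions: true  # scale efficacy reductions by SEN
  los_gating: all                   # "all" | "sen"
  treat_trigger: adjusted           # "adjusted" | "usual"
  half_cycle: false
  discount_life_years: true
  life_year_basis: end              # "end" | "start"
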