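# National inputs and calibrated survey-derived inputs, Romania, reference
# year 2022.  Epidemiology: GBD 2021 crude counts.  Survey margins are the
# integer severity counts of the two collected cohorts.  Cost averages are
# the per-severity per-patient annual input averages (EUR).  Worker shares
# and per-worker mean absence days are reproduction fixtures back-solved
# from the published national worker counts and productivity totals (the
# underlying survey-internal margins were never published); caregiver day
# inputs differ by epidemiological basis because the published totals are
# not jointly consistent with a single per-worker mean.
epi:
  prevalence_under20: 102783
  prevalence_20plus: 52801
  incidence_under20: 13125
  incidence_20plus: 8516
  hospital_discharges_total: 1209

unit_costs:
  gross_monthly_wage: 6126.0
  part_time_monthly_wage: 3063.0
  working_days_per_year: 251
  alos_adult: 7.95
  alos_pediatric: 4.44
  hospital_cost_per_day_adult: 1094.0
  hospital_cost_per_day_pediatric: 1012.0
  avg_prescription: 40.4
  fx: 4.9315
  hospital_cost_basis: per_day

survey_margins:
  adult: {mild: 141, moderate: 368, severe: 113}
  pediatric: {mild: 22, moderate: 21, severe: 14}

cost_averages_eur:   # order: [mild, moderate, severe]
  adult:
    cost_treatment: [116.4, 125.3, 266.5]
    cost_medical_services: [61.2, 158.3, 371.9]
    cost_associated: [71.3, 97.7, 219.2]
  pediatric:
    cost_treatment: [89.0, 131.0, 206.4]
    cost_medical_services: null
    cost_associated: [109.0, 177.0, 427.3]

worker_shares:       # fraction of stratum cases, [mild, moderate, severe]
  adult:
    full_time: [0.180717, 0.548190, 0.271031]
    part_time: [0.124990, 0.687506, 0.187533]
  pediatric:
    full_time: [0.3333333333, 0.4444444444, 0.2222222222]
    part_time: [0.0, 1.0, 0.0]

mean_days_missed:    # per worker per year, [mild, moderate, severe]
  adult:             # consistent across both bases
    full_time: [0.83338, 0.90271, 2.63532]
    part_time: [3.57188, 6.16907, 8.33151]
  pediatric:
    prevalence:
      full_time: [8.57147, 11.78616, 10.71470]
      part_time: [0.0, 66.96761, 0.0]
    incidence:
      full_time: [25.70922, 47.14696, 21.44137]
      part_time: [0.0, 267.84023, 0.0]
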