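{
  "arms": {
    "digital_cbt": {
      "remission_prob_cycle1": 0.60,
      "attrition_prob": 0.16,
      "treatment_cost": 400.00,
      "attrition_cost_fraction": 1.0
    },
    "individual_cbt": {
      "remission_prob_cycle1": 0.60,
      "attrition_prob": 0.09,
      "treatment_cost": 2788.50,
      "attrition_cost_fraction": 0.16666666666666666
    },
    "group_cbt": {
      "remission_prob_cycle1": 0.60,
      "attrition_prob": 0.24,
      "treatment_cost": 579.15,
      "attrition_cost_fraction": 0.16666666666666666
    },
    "pharmacotherapy": {
      "remission_prob_cycle1": 0.50,
      "attrition_prob": 0.30,
      "treatment_cost": 236.69,
      "attrition_cost_fraction": 0.16666666666666666
    },
    "no_treatment": {
      "remission_prob_cycle1": 0.15,
      "attrition_prob": 0.0,
      "treatment_cost": 0.0,
      "attrition_cost_fraction": 0.0
    }
  },
  "disease": {
    "physician_visit_cost": 195.25,
    "physician_visits_gad": 4.4,
    "physician_visits_healthy": 2.4,
    "er_cost": 1004.70,
    "er_prob_gad": 0.05,
    "er_prob_healthy": 0.028,
    "hospitalization_cost": 5722.00,
    "hosp_prob_gad": 0.05,
    "hosp_prob_healthy": 0.028,
    "daily_wage": 206.00,
    "disability_days_gad": 21.4,
    "disability_days_healthy": 7.8,
    "median_hourly_wage": 27.72
  },
  "globals": {
    "utility_gad": 0.66,
    "utility_healthy": 0.80,
    "annual_discount_rate": 0.03,
    "wtp_per_qaly": 50000.0,
    "cycle_length": 0.5,
    "n_cycles": 2,
    "cohort_size_per_arm": 20000,
    "natural_remission_prob": 0.15
  }
}
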