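# Default model inputs: eight-arm post-stroke prophylaxis comparison,
# Dutch health-care payer perspective, 2024 euros.
# 90-day mRS probability vectors may sum to 0.99-1.01 due to rounding in the
# source; they are renormalized on load.

mrs_probabilities:
  SoC:         [0.07, 0.07, 0.09, 0.21, 0.19, 0.12, 0.24]
  Par:         [0.02, 0.10, 0.10, 0.25, 0.19, 0.15, 0.19]
  Cef:         [0.06, 0.09, 0.17, 0.15, 0.22, 0.12, 0.19]
  Cef-Par:     [0.05, 0.07, 0.09, 0.19, 0.19, 0.13, 0.28]
  Met:         [0.04, 0.10, 0.13, 0.21, 0.13, 0.16, 0.23]
  Met-Par:     [0.05, 0.11, 0.13, 0.18, 0.19, 0.14, 0.20]
  Met-Cef:     [0.03, 0.12, 0.14, 0.21, 0.14, 0.16, 0.20]
  Met-Cef-Par: [0.07, 0.10, 0.14, 0.13, 0.17, 0.14, 0.25]

recurrence:
  weibull_log_shape: -0.57
  weibull_log_scale: 5.49
  # Time unit of the Weibull scale exp(log_scale). With the default "years"
  # the baseline cumulative recurrence risk is ~4.5% at 1 y and ~16% at 10 y,
  # matching the registry data the curve was calibrated to.
  weibull_time_unit: years
  # Hazard ratios by mRS group {0, 1-2, 3+}, normalized on the SoC case mix.
  hazard_ratios: [1.0, 1.18, 1.36]
  # One-off acute-care cost charged when a recurrent stroke occurs.
  acute_cost_per_event: 0.0

mortality:
  # Weekly other-cause rates at the anchor ages; log-linear in between,
  # clamped above age 99.
  weekly_rate_age80: 0.001
  weekly_rate_age99: 0.008
  hazard_ratio_mrs0: 1.20
  hazard_ratios_mrs1_5: [1.42, 1.87, 2.17, 3.1, 6.91]

utilities:
  # EQ-5D-5L utility weights by mRS 0-6 (mRS 6 = death = 0 by definition).
  mrs0_6: [0.94, 0.85, 0.78, 0.59, 0.30, 0.14, 0.00]

length_of_stay_days:
  # Mean days per location during the 90-day acute phase, by mRS 0-6.
  hospital:       [8.9, 9.8, 14.5, 18.9, 24.9, 29.7, 14.9]
  rehabilitation: [5.6, 7.9, 16.0, 29.7, 39.5, 31.2, 4.1]
  nursing_home:   [0.0, 0.7, 0.6, 2.4, 9.0, 16.0, 3.4]
  home:           [75.4, 71.5, 59.0, 39.0, 16.6, 13.1, 3.5]

procedures:
  ivt_proportion_mrs0_6: [0.43, 0.54, 0.57, 0.52, 0.44, 0.40, 0.43]
  evt_proportion_mrs0_6: [0.20, 0.30, 0.30, 0.24, 0.29, 0.28, 0.23]
  carotid_endarterectomy_proportion: 0.06

unit_costs:
  hospital_per_day: 683
  rehabilitation_per_day: 379
  nursing_home_per_day: 308
  visits_per_patient: 250
  diagnostics_per_patient: 586
  allied_health_per_patient: 257
  carotid_endarterectomy: 5426
  intravenous_thrombolysis: 1130
  endovascular_thrombectomy: 11797
  intravenous_infusion: 180

drug_costs_per_patient:
  Met: 1.08
  Par: 1.60
  Cef: 74.72

# The infusion cost is charged once per course for strategies containing the
# IV-only drug (ceftriaxone); set to "all" to charge every active arm.
infusion_rule: cef_only

long_term_care:
  # Weekly long-term care cost by mRS 0-5 (euro); death accrues none.
  weekly_cost_mrs0_5: [127, 127, 183, 412, 925, 1208]

indirect_costs:
  # Age-related per-capita indirect medical costs, euro per week, linear
  # between the anchors and clamped above age 99.
  enabled: true
  weekly_at_age80: 0.0
  weekly_at_age99: 704.0

economics:
  cost_discount_rate: 0.03
  qaly_discount_rate: 0.015
  thresholds: [20000, 50000, 80000]
  horizon_years: 20
  cycle_length_weeks: 1
  start_age: 80
  max_age: 100

population:
  # Age/sex-matched general-population quality-adjusted life expectancy used
  # for the proportional-shortfall calculation (external input).
  general_population_qale: 6.61

uncertainty:
  # Effective sample size behind each arm's Dirichlet mRS distribution
  # (trial total 1,493 split evenly over 8 arms).
  dirichlet_ess: 186.625
  gamma_cv: 0.2          # costs, lengths of stay, procedure proportions
  beta_se: 0.02          # utilities, carotid proportion
  lognormal_cv: 0.1      # hazard ratios
  normal_se_log_weibull: 0.1   # SE of the Weibull log-shape / log-scale
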