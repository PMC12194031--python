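# Default configuration for the difelikefalin vs best-supportive-care
# cost-utility model.  Every field shown here mirrors the packaged
# defaults; delete a section to fall back to it wholesale.

cohort:
  n_per_arm: 500
  baseline_mean: 18.0        # 5-D Itch score units; entry truncated to [12, 25]
  baseline_sd: 3.0
  # Week-12 mean score change by arm and baseline severity stratum
  # (negative = improvement).  Calibrated with change_sd so the arms'
  # >= 5-point response proportions are 52.1% / 42.3%.
  change_mean_by_arm_and_stratum:
    difelikefalin: {moderate: -4.08, severe: -5.08, very_severe: -6.08}
    placebo: {moderate: -3.18, severe: -3.68, very_severe: -4.18}
  change_sd: 5.0
  response_threshold: 5      # score-point MCID of the 5-D Itch scale
  female_fraction: 0.4
  weight_mean_kg: 75.0
  weight_sd_kg: 15.0
  seed: 0

schedule:
  run_in_cycles: 3
  run_in_cycle_weeks: 4
  main_cycle_weeks: 52
  horizon_years: 42          # lifetime horizon
  half_cycle_correction: false

responder_rule:
  criterion: category_improvement   # or point_improvement (threshold 5)
  threshold: 1

hazards:                      # all-cause mortality HR vs no pruritus
  hr_none: 1.0
  hr_mild: 1.0
  hr_moderate: 1.11
  hr_severe: 1.02
  hr_very_severe: 1.24

demographics:
  start_age_years: 59.0
  female_fraction: 0.4

health_state_values:
  utility:
    none: 0.744
    mild: 0.726
    moderate: 0.589
    severe: 0.595
    very_severe: 0.595
    transplant: 0.712
  annual_state_cost:          # GBP/year, excludes dialysis
    none: 3726.0
    mild: 3753.0
    moderate: 3891.0
    severe: 4084.0
    very_severe: 4304.0
  bsc_cost:                   # GBP/year; moderate tied to mild, very severe to severe
    none: 31.98
    mild: 42.48
    moderate: 42.48
    severe: 75.65
    very_severe: 75.65

drug_cost:
  vial_price: 31.90           # GBP per single-use vial
  dose_per_kg: 0.5            # micrograms per kg dry body weight
  vial_content: 65.0          # micrograms per vial (configuration default)
  sessions_per_week: 2.96
  weeks_per_year: 52.0

economics:
  discount_rate_annual: 0.035
  ae_cost_per_event: 33.19    # one GP appointment per adverse event
  ae_events_per_patient_year: {difelikefalin: 0.10, bsc: 0.10}
  ae_qaly_loss: 0.0
  transplant_cost_once: 17000.0        # synthetic default
  posttransplant_annual_cost: 5000.0   # synthetic default
  wtp_thresholds: [30000.0, 40000.0, 50000.0]

waning_horizon_years: 10.0    # BSC arm back at baseline severity mix by year 10
# survival_schedule_path / life_table_path default to the packaged
# synthetic fixtures when omitted.
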