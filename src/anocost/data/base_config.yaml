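# Default model configuration.
#
# Sensitivity bounds are the published one-way analysis ranges (2010/11
# National Tariff / Reference Cost scale).  Base unit costs are
# illustrative: midpoints of the published bounds where bounds exist,
# otherwise plausible 2010/11 tariff-scale values.  Replace with a
# transcribed base-case parameter file for a production analysis.

model:
  n_cycles: 120                 # ten-year horizon, monthly cycles
  annual_inflation: 0.032       # constant 2011/12-level CPI rate (inflated scenario)
  palliative_duration_months: 12  # expected palliative duration, advanced presentation

# Monthly transition probabilities (replace with a calibration run).
probabilities:
  p_relapse: 0.005
  p_death_df: 0.004
  p_death_pr: 0.030

calibration:
  ranges:
    p_relapse: [0.0, 0.03]
    p_death_df: [0.0, 0.02]
    p_death_pr: [0.0, 0.10]
  batch_size: 1000
  contraction: 0.5
  max_rounds: 20
  sig_figs: 3

unit_costs:
  mri: 324.0            # staging MRI (bounds 235-413)
  ct: 146.5             # staging CT (bounds 116-177)
  fna: 442.5            # fine needle aspiration (bounds 269-616)
  eua_biopsy: 1457.0    # examination under anaesthetic / biopsy (bounds 1117-1797)
  mitomycin_c: 44.0     # bounds 40-48
  followup_appointment: 130.0
  followup_mri: 324.0   # follow-up MRI (bounds 235-413)
  followup_ct: 146.5    # follow-up CT (bounds 116-177)
  salvage_apr: 8000.0   # abdominoperineal resection
  reconstruction: 2500.0
  colostomy: 3500.0
  palliative_monthly: 1000.0

primary_treatment:
  n_rt_fractions: 25
  n_fu5_cycles: 2
  admission_costs:
    # elective inpatient row: midpoints of the staging/primary-treatment bounds
    elective:
      rt_planning: 991.5
      picc_insertion: 645.5
      fu5_procure: 273.5
      fu5_deliver_initial: 316.5
      fu5_deliver_subsequent: 276.5
      rt_delivery: 128.0
    # day case: lower values of the admission-type bounds
    day_case:
      rt_planning: 729.0
      picc_insertion: 751.0
      fu5_procure: 286.0
      fu5_deliver_initial: 302.0
      fu5_deliver_subsequent: 206.0
      rt_delivery: 111.0
    # non-elective: upper values of the admission-type bounds
    non_elective:
      rt_planning: 2869.0
      picc_insertion: 2068.0
      fu5_procure: 339.0
      fu5_deliver_initial: 334.0
      fu5_deliver_subsequent: 294.0
      rt_delivery: 261.0

proportions:
  p_crt: 0.85          # fraction treated with chemoradiotherapy (vs RT alone)
  p_advanced: 0.05     # fraction presenting with advanced disease (palliative branch)
  p_salvage: 0.5       # fraction of relapses undergoing salvage APR
  p_colostomy: 0.05    # fraction receiving pre-treatment colostomy
  p_fna: 0.25          # fraction receiving fine needle aspiration at staging
  admission_mix:       # 85% elective overall, of which 33%-points day case
    elective: 0.52
    day_case: 0.33
    non_elective: 0.15

followup:
  programme_months: 120
  low:                 # low risk of relapse (CRT arm)
    appointments: 16
    mri_scans: 1
    ct_scans: 1
  high:                # high risk of relapse (RT-alone arm)
    appointments: 16
    mri_scans: 6
    ct_scans: 3

# One-way sensitivity variable blocks: each block is varied jointly to
# its low values, then to its high values, all else at base.
sensitivity:
  - name: "Admission type for primary treatment"
    members: ["proportions.admission_mix"]
    low:
      - {elective: 0.0, day_case: 1.0, non_elective: 0.0}
    high:
      - {elective: 0.0, day_case: 0.0, non_elective: 1.0}
  - name: "Cost of staging/primary treatment"
    members:
      - unit_costs.mri
      - unit_costs.ct
      - unit_costs.fna
      - unit_costs.eua_biopsy
      - unit_costs.mitomycin_c
      - primary_treatment.admission_costs.elective.rt_planning
      - primary_treatment.admission_costs.elective.picc_insertion
      - primary_treatment.admission_costs.elective.fu5_procure
      - primary_treatment.admission_costs.elective.fu5_deliver_initial
      - primary_treatment.admission_costs.elective.fu5_deliver_subsequent
      - primary_treatment.admission_costs.elective.rt_delivery
    low: [235.0, 116.0, 269.0, 1117.0, 40.0, 674.0, 414.0, 187.0, 232.0, 210.0, 122.0]
    high: [413.0, 177.0, 616.0, 1797.0, 48.0, 1309.0, 877.0, 360.0, 401.0, 343.0, 134.0]
  - name: "Monthly costs of palliative care"
    members: [unit_costs.palliative_monthly]
    low: [500.0]
    high: [1500.0]
  - name: "Intensity of follow-up"
    members:
      - followup.low.appointments
      - followup.low.mri_scans
      - followup.low.ct_scans
      - followup.high.appointments
      - followup.high.mri_scans
      - followup.high.ct_scans
    low: [14, 0, 0, 14, 5, 2]
    high: [18, 2, 2, 18, 7, 4]
  - name: "Proportion of patients undergoing salvage surgery"
    members: [proportions.p_salvage]
    low: [0.25]
    high: [0.75]
  - name: "Proportion of patients presenting with advanced disease"
    members: [proportions.p_advanced]
    low: [0.025]
    high: [0.10]
  - name: "Cost of follow-up interventions"
    members: [unit_costs.followup_mri, unit_costs.followup_ct]
    low: [235.0, 116.0]
    high: [413.0, 177.0]
  - name: "Proportion of patients receiving chemo radiotherapy"
    members: [proportions.p_crt]
    low: [0.70]
    high: [0.95]
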