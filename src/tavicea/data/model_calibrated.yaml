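# Calibrated model configuration.
#
# Identical to model_default.yaml except for the explicitly calibrated
# under-determined choices, solved against the published per-patient base-case
# results (TAVI 720,257,876 IRR / 1.27 QALYs; SAVR 352,077,775 IRR / 0.90):
#   * long-term (cycle >= 2) annual all-cause death probabilities per arm
#     (USER_TABLE), matching the arm QALY totals;
#   * valve-cost procedure-phase weights per arm (the share of the 800M
#     valve cost borne by each strategy's procedure phase), matching the
#     arm cost totals.
# See docs/methods.md ("Calibration") for the derivation.

utilities:
  mean_by_nyha: {I: 0.72, II: 0.72, III: 0.53, IV: 0.47}
  sd_by_nyha: {I: 0.25, II: 0.25, III: 0.32, IV: 0.35}
  stroke_disutility: 0.39

events:
  followup_years: 5.0
  TAVI:
    tia: 0.053
    stroke: 0.153
    rehospitalization: 0.333
    myocardial_infarction: 0.111
    new_atrial_fibrillation: 0.158
    new_pacemaker: 0.155
    aortic_valve_reintervention: 0.032
  SAVR:
    tia: 0.043
    stroke: 0.125
    rehospitalization: 0.252
    myocardial_infarction: 0.082
    new_atrial_fibrillation: 0.304
    new_pacemaker: 0.13
    aortic_valve_reintervention: 0.008

entry:
  TAVI: {NYHA1: 0.36, NYHA2: 0.28, NYHA3: 0.10, NYHA4: 0.01, death: 0.25}
  SAVR: {NYHA1: 0.34, NYHA2: 0.30, NYHA3: 0.07, NYHA4: 0.02, death: 0.27}

costs:
  - name: tavi_procedure
    mean: 20052000
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: PROCEDURE}
  - name: savr_procedure
    mean: 12811000
    sampling: FIXED
    assignment:
      - {arm: SAVR, phase: PROCEDURE}
  - name: tavi_hospitalization
    mean: 43200000
    sd: 4032654
    sampling: GAMMA
    assignment:
      - {arm: TAVI, phase: PROCEDURE}
      - {arm: TAVI, phase: PER_CYCLE_EVENT, event: rehospitalization}
  - name: savr_hospitalization
    mean: 75750000
    sd: 4326731
    sampling: GAMMA
    assignment:
      - {arm: SAVR, phase: PROCEDURE}
      - {arm: SAVR, phase: PER_CYCLE_EVENT, event: rehospitalization}
  - name: tavi_stent
    mean: 450000000
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: PROCEDURE}
  - name: valve
    mean: 800000000
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: ACUTE_EVENT, event: aortic_valve_reintervention}
      - {arm: SAVR, phase: ACUTE_EVENT, event: aortic_valve_reintervention}
      - {arm: TAVI, phase: PROCEDURE, weight: 0.212270}
      - {arm: SAVR, phase: PROCEDURE, weight: 0.309648}
  - name: pacemaker_icd
    mean: 9183500
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: ACUTE_EVENT, event: new_pacemaker}
      - {arm: SAVR, phase: ACUTE_EVENT, event: new_pacemaker}
  - name: angioplasty
    mean: 7398300
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: ACUTE_EVENT, event: myocardial_infarction}
      - {arm: SAVR, phase: ACUTE_EVENT, event: myocardial_infarction}
  - name: reoperation_tavi
    mean: 10026000
    sd: 1430401
    sampling: GAMMA
    assignment:
      - {arm: TAVI, phase: ACUTE_EVENT, event: aortic_valve_reintervention}
  - name: reoperation_savr
    mean: 6405500
    sd: 2720528
    sampling: GAMMA
    assignment:
      - {arm: SAVR, phase: ACUTE_EVENT, event: aortic_valve_reintervention}
  - name: cabg
    mean: 22280000
    sampling: FIXED
    assignment:
      - {arm: TAVI, phase: ACUTE_EVENT, event: myocardial_infarction}
      - {arm: SAVR, phase: ACUTE_EVENT, event: myocardial_infarction}

econ:
  discount_rate: 0.065
  exchange_rate: 250000
  # WHO thresholds: 1x and 3x Iran's 2020 GDP per capita, plus a surrounding
  # grid for the acceptability curve.
  wtp_grid:
    [0, 250000000, 500000000, 551400000, 750000000, 1000000000, 1250000000,
     1500000000, 1654200000, 2000000000, 2250000000, 2500000000, 2750000000,
     3000000000]
  cycle_length_years: 1.0
  max_cycles: 50
  survival_stop_epsilon: 1.0e-4
  half_cycle_correction: false

knobs:
  longterm_death_mode: USER_TABLE
  death_table:
    TAVI: [[2, 0.223587]]
    SAVR: [[2, 0.333156]]
  event_annualization: CUMULATIVE_OVER_FOLLOWUP
  rehospitalization_recurring: true
  owsa_mode: MULTIPLIER
  owsa_grid: [0.05, 0.25, 0.50, 0.75, 1.00, 1.50, 2.00, 2.50]
  psa_icer_summary: RATIO_OF_MEANS
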