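# Default model configuration: TAVI vs SAVR cost-effectiveness, Iran 2020.
# Utilities are EQ-5D weights by NYHA class; event probabilities are
# cumulative over the five-year trial follow-up; costs are 2020 Iranian Rial
# from the national fee schedule. The cost-assignment table (which arm and
# phase each item accrues to, and which adverse event triggers it) is data,
# not code: edit it here to explore alternative mappings.

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
  longterm_death_mode: CONSTANT_YEAR1
  event_annualization: CUMULATIVE_OVER_FOLLOWUP
  rehospitalization_recurring: true
  owsa_mode: MULTIPLIER
  owsa_grid: [0.05, 0.25, 0.50, 0.75, 1.00, 1.50, 2.00, 2.50]
  psa_icer_summary: RATIO_OF_MEANS
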