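# First-line advanced/metastatic ESCC in China: camrelizumab + paclitaxel/cisplatin
# versus placebo + paclitaxel/cisplatin. Costs in 2020 USD ($1 = ¥6.9).
# Weibull survival parameters were fitted to the trial's digitized
# Kaplan-Meier curves; scale is per month^shape, time unit is months.
name: escort1st
arms:
  - name: camrelizumab-chemotherapy
    pfs:
      scale: 0.035843
      shape: 1.440454
      se_scale: 0.007191
      se_shape: 0.082920
      ci_scale: [0.024190, 0.053110]
      ci_shape: [1.286766, 1.612498]
    os:
      scale: 0.005274
      shape: 1.798021
      se_scale: 0.001911
      se_shape: 0.135765
      ci_scale: [0.002593, 0.010729]
      ci_shape: [1.550680, 2.084815]
    ae_risks:
      anemia: 0.174
      white_blood_cell_decreased: 0.242
      neutrophil_decreased: 0.399
    regimen:
      - drug: camrelizumab
        price_per_unit: 424.35
        unit_size: 200
        dose_mode: flat_mg
        dose: 200
        schedule_days: 21
        max_administrations: null        # until progression
      - drug: paclitaxel
        price_per_unit: 108.26
        unit_size: 100
        dose_mode: per_m2
        dose: 175
        schedule_days: 21
        max_administrations: 6
      - drug: cisplatin
        price_per_unit: 10.97
        unit_size: 100
        dose_mode: per_m2
        dose: 75
        schedule_days: 21
        max_administrations: 6
  - name: placebo-chemotherapy
    pfs:
      scale: 0.030222
      shape: 1.824045
      se_scale: 0.005986
      se_shape: 0.092109
      ci_scale: [0.020499, 0.044558]
      ci_shape: [1.652161, 2.013811]
    os:
      scale: 0.006991
      shape: 1.818036
      se_scale: 0.002212
      se_shape: 0.120060
      ci_scale: [0.003760, 0.013000]
      ci_shape: [1.597315, 2.069258]
    ae_risks:
      anemia: 0.135
      white_blood_cell_decreased: 0.266
      neutrophil_decreased: 0.434
    regimen:
      - drug: paclitaxel
        price_per_unit: 108.26
        unit_size: 100
        dose_mode: per_m2
        dose: 175
        schedule_days: 21
        max_administrations: 6
      - drug: cisplatin
        price_per_unit: 10.97
        unit_size: 100
        dose_mode: per_m2
        dose: 75
        schedule_days: 21
        max_administrations: 6
econ:
  unit_costs:
    followup_per_cycle: 73.57
    labs_radiology: 356.60
    salvage_per_cycle: 638.43
    bsc_per_cycle: 167.29
    terminal_care: 1460.30
  ae_unit_costs:
    anemia: 508.2
    white_blood_cell_decreased: 466.00
    neutrophil_decreased: 534.40
  utilities:
    pfs: 0.68
    pd: 0.42
  bsa: 1.72
  discount_rate: 0.03
  wtp: 31498.70
  horizon_cycles: 60
  cycle_months: 1
  bg_annual_mortality: 0.00707
run:
  seed: 2021
  psa_n: 1000
  policies:
    pd_death_rule: os_calibrated
    membership: cycle_start
    vial_rounding: false
    labs_accrual: per_cycle_pfs
    bridging: calendar
    subtract_bg_from_progression: true
distributions:
  drug_price.camrelizumab: {kind: triangle, base: 424.35, low: 339.40, high: 509.10}
  drug_price.paclitaxel: {kind: triangle, base: 108.26, low: 86.61, high: 129.91}
  drug_price.cisplatin: {kind: triangle, base: 10.97, low: 8.78, high: 13.16}
  cost.followup_per_cycle: {kind: triangle, base: 73.57, low: 58.86, high: 88.28}
  cost.labs_radiology: {kind: triangle, base: 356.60, low: 285.28, high: 427.92}
  cost.salvage_per_cycle: {kind: triangle, base: 638.43, low: 510.74, high: 766.12}
  cost.bsc_per_cycle: {kind: triangle, base: 167.29, low: 133.83, high: 200.75}
  cost.terminal_care: {kind: triangle, base: 1460.30, low: 1168.24, high: 1752.36}
  ae_cost.anemia: {kind: triangle, base: 508.2, low: 381.2, high: 635.3}
  ae_cost.white_blood_cell_decreased: {kind: triangle, base: 466.00, low: 372.80, high: 559.20}
  ae_cost.neutrophil_decreased: {kind: triangle, base: 534.40, low: 427.52, high: 641.28}
  ae_risk.camrelizumab-chemotherapy.anemia: {kind: beta, base: 0.174, low: 0.1392, high: 0.2088}
  ae_risk.camrelizumab-chemotherapy.white_blood_cell_decreased: {kind: beta, base: 0.242, low: 0.1936, high: 0.2904}
  ae_risk.camrelizumab-chemotherapy.neutrophil_decreased: {kind: beta, base: 0.399, low: 0.3192, high: 0.4788}
  ae_risk.placebo-chemotherapy.anemia: {kind: beta, base: 0.135, low: 0.1080, high: 0.1620}
  ae_risk.placebo-chemotherapy.white_blood_cell_decreased: {kind: beta, base: 0.266, low: 0.2128, high: 0.3192}
  ae_risk.placebo-chemotherapy.neutrophil_decreased: {kind: beta, base: 0.434, low: 0.3472, high: 0.5208}
  utility.pfs: {kind: beta, base: 0.68, low: 0.54, high: 0.82}
  utility.pd: {kind: beta, base: 0.42, low: 0.34, high: 0.50}
  bsa: {kind: triangle, base: 1.72, low: 1.38, high: 2.06}
  discount_rate: {kind: fixed, base: 0.03, low: 0.00, high: 0.08}
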