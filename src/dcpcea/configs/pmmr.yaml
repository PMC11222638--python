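# Mismatch-repair-proficient (pMMR) subgroup base case.
# Identical cost/utility/adverse-event inputs to the dMMR scenario; only the
# fitted survival models differ.
subgroup: pMMR
discount_rate: 0.03
wtp: 150000.0

horizon:
  start_age: 64.0
  end_age: 82.0
  cycle_days: 21.0

survival_models:
  DCP:
    pfs: {family: log_normal, params: {meanlog: 2.49712, sdlog: 1.07087}}
    os: {family: log_normal, params: {meanlog: 3.77032, sdlog: 1.33401}}
  CP:
    pfs: {family: log_logistic, params: {shape: 1.87448, scale: 9.19005}}
    os: {family: log_logistic, params: {shape: 1.78643, scale: 27.54835}}

costs:
  dostarlimab_per_10mg: 233.258
  pembrolizumab_per_mg: 55.730
  doxorubicin_per_10mg: 3.279
  paclitaxel_per_mg: 0.108
  carboplatin_per_50mg: 3.599
  imaging_per_scan: 651.81
  labs_per_cycle: 359.16
  administration_per_cycle: 149.69
  physician_visit_per_cycle: 164.04
  end_of_life: 37590.23
  bsc_per_cycle: 1300.61
  bsa: 1.84
  gfr: 70.0
  carboplatin_auc: 5.0
  subsequent_fraction_dcp: 0.283
  subsequent_fraction_cp: 0.585
  doxorubicin_split: 0.05
  pembrolizumab_cap_months: null
  whole_vial: false

utilities:
  u_pfs: 0.817
  u_pd: 0.779
  u_death: 0.0

adverse_events:
  DCP:
    - {name: anemia, incidence: 0.149, cost: 14757.94, disutility: 0.073}
    - {name: neutropenia, incidence: 0.095, cost: 14809.28, disutility: 0.09}
    - {name: neutrophil_count_decreased, incidence: 0.083, cost: 14809.28, disutility: 0.09}
    - {name: lymphocyte_count_decreased, incidence: 0.054, cost: 7257.66, disutility: 0.09}
    - {name: white_cell_count_decreased, incidence: 0.066, cost: 7257.66, disutility: 0.09}
    - {name: hypertension, incidence: 0.071, cost: 8212.53, disutility: 0.05}
    - {name: pulmonary_embolism, incidence: 0.050, cost: 87717.73, disutility: 0.10}
    - {name: hypokalemia, incidence: 0.050, cost: 7332.99, disutility: 0.05}
  CP:
    - {name: anemia, incidence: 0.163, cost: 14757.94, disutility: 0.073}
    - {name: neutropenia, incidence: 0.093, cost: 14809.28, disutility: 0.09}
    - {name: neutrophil_count_decreased, incidence: 0.138, cost: 14809.28, disutility: 0.09}
    - {name: lymphocyte_count_decreased, incidence: 0.073, cost: 7257.66, disutility: 0.09}
    - {name: white_cell_count_decreased, incidence: 0.053, cost: 7257.66, disutility: 0.09}
    - {name: hypertension, incidence: 0.033, cost: 8212.53, disutility: 0.05}
    - {name: pulmonary_embolism, incidence: 0.049, cost: 87717.73, disutility: 0.10}
    - {name: hypokalemia, incidence: 0.037, cost: 7332.99, disutility: 0.05}
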