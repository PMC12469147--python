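# Chinese healthcare-system perspective (costs in 2023 US$, exchange rate 7.0467 CNY/$).
# All healthcare-related expenses are included; benmelstobart and anlotinib patient
# payments are capped at 4 cycles by assistance programs (drug free thereafter,
# administration continues while on treatment).
perspective: china
wtp_per_qaly: 38042.49   # 3x 2023 GDP per capita

plan:
  cycle_length_days: 21.0
  horizon_years: 10.0
  discount_rate: 0.05
  half_cycle_correction: true
  curve_timescale: cycle_month   # frozen base-case grid; see docs/methods.md

survival_models:
  combo:
    os:  {family: lognormal, params: {meanlog: 2.9149, sdlog: 0.9062}}
    pfs: {family: generalized_gamma, params: {mu: 1.9133, sigma: 0.6989, Q: -0.7736}}
  control:
    os:  {family: loglogistic, params: {shape: 2.4470, scale: 12.8850}}
    pfs: {family: loglogistic, params: {shape: 4.4280, scale: 5.0570}}

utilities: {pfs: 0.69, pd: 0.60}

unit_costs:          # $ per 21-day cycle unless one-time
  benmelstobart: 3485.32
  anlotinib: 563.24
  carboplatin: 51.26
  etoposide: 6.63
  topotecan: 246.69
  laboratory_test: 92.99
  pet_ct: 912.28
  end_of_life: 1460.30          # one-time, at death
  best_supportive_care: 345.60
  administration_per_iv_cycle: 134.93   # 93.93 prophylaxis/IV + 1.86 infusion + 39.14 premedication

ae:                  # grade >=3 events, charged once in cycle 1
  anemia:           {cost: 138.75,  disutility: 0.073, incidence: {combo: 0.2398, control: 0.2358}}
  thrombocytopenia: {cost: 1505.92, disutility: 0.05,  incidence: {combo: 0.4959, control: 0.3577}}
  neutropenia:      {cost: 115.01,  disutility: 0.20,  incidence: {combo: 0.6951, control: 0.6870}}
  hypertension:     {cost: 120.00,  disutility: 0.12,  incidence: {combo: 0.1545, control: 0.0162}}

subsequent_treatment:
  drug: topotecan
  mode: one_time     # expected cost of a fixed course at PD entry
  cycles: 4
  proportion: {combo: 0.4268, control: 0.7126}

care_scopes:         # healthcare-system perspective: all living patients
  monitoring: alive
  pet: alive
  bsc: alive
pet_every_n_cycles: 2
ae_disutility_cycles: 1

arms:
  combo:
    label: benmelstobart_anlotinib_chemo
    maintenance_drugs: [benmelstobart, anlotinib]
    paid_maintenance_cycles: 4   # assistance-program cap; null = paid to progression
    chemo_drugs: [carboplatin, etoposide]
    chemo_cycles: 4
    admin_scope: pfs             # IV administration continues while progression-free
  control:
    label: chemotherapy
    maintenance_drugs: []
    paid_maintenance_cycles: null
    chemo_drugs: [carboplatin, etoposide]
    chemo_cycles: 4
    admin_scope: chemo

owsa:
  relative_range: 0.20
  explicit_ranges:
    discount_rate: [0.04, 0.06]

dosing_reference:    # Calvert / BSA dosing cross-check only; costs above are per-cycle
  bsa_m2: 1.72
  weight_kg: 65
  carboplatin_auc: 5
  gfr_ml_min: 90
  etoposide_mg_per_m2: 100
  etoposide_days: 3

price_simulation:
  drug: benmelstobart
  grid_per_1200mg: [0.0, 8000.0]
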