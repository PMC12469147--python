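# US payer perspective (direct medical costs only; 3% annual discount).
# Benmelstobart priced at 80% of atezolizumab, anlotinib at 3.4x its Chinese
# price (comparative price index); no assistance programs, so maintenance
# drugs are paid while progression-free.
perspective: us
wtp_per_qaly: 150000.00

plan:
  cycle_length_days: 21.0
  horizon_years: 10.0
  discount_rate: 0.03
  half_cycle_correction: true
  curve_timescale: cycle_month

survival_models:
  combo:
    os:  {family: lognormal, params: {meanlog: 2.9149, sdlog: 0.9062}}
    pfs: {family: generalized_gamma, params: {mu: 1.9133, sigma: 0.6989, Q: -0.7736}}
  control:
    os:  {family: loglogistic, params: {shape: 2.4470, scale: 12.8850}}
    pfs: {family: loglogistic, params: {shape: 4.4280, scale: 5.0570}}

utilities: {pfs: 0.69, pd: 0.60}

unit_costs:
  benmelstobart: 8469.41
  anlotinib: 1915.02
  carboplatin: 55.83
  etoposide: 62.76
  topotecan: 2720.26
  laboratory_test: 111.65
  pet_ct: 1769.89
  end_of_life: 21603.00
  best_supportive_care: 1447.79
  administration_per_iv_cycle: 173.23   # 142.55 first hour + 30.68 additional hour

ae:                  # trial incidences re-priced at US management costs
  anemia:           {cost: 7941.00,  disutility: 0.073, incidence: {combo: 0.2398, control: 0.2358}}
  thrombocytopenia: {cost: 13105.00, disutility: 0.05,  incidence: {combo: 0.4959, control: 0.3577}}
  neutropenia:      {cost: 13105.00, disutility: 0.20,  incidence: {combo: 0.6951, control: 0.6870}}
  hypertension:     {cost: 15811.00, disutility: 0.12,  incidence: {combo: 0.1545, control: 0.0162}}

subsequent_treatment:
  drug: topotecan
  mode: per_cycle    # ongoing second-line therapy through the PD state
  cycles: 4
  proportion: {combo: 0.4268, control: 0.7126}

care_scopes:         # payer perspective: direct costs of active management
  monitoring: pfs
  pet: pfs
  bsc: pd
pet_every_n_cycles: 2
ae_disutility_cycles: 1

arms:
  combo:
    label: benmelstobart_anlotinib_chemo
    maintenance_drugs: [benmelstobart, anlotinib]
    paid_maintenance_cycles: null   # paid to progression
    chemo_drugs: [carboplatin, etoposide]
    chemo_cycles: 4
    admin_scope: pfs
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
    discount_rate: [0.024, 0.036]

dosing_reference:
  bsa_m2: 1.79
  weight_kg: 65
  carboplatin_auc: 5
  gfr_ml_min: 90
  etoposide_mg_per_m2: 100
  etoposide_days: 3

price_simulation:
  drug: benmelstobart
  grid_per_1200mg: [0.0, 8000.0]
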