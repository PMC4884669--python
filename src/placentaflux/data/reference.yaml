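# Packaged physiological reference configuration.
# Units: concentrations umol/l, maximum rates umol/min, volumes ml,
# specific flows ml/min/g, membrane potential V, temperature K.
geometry:
  total_volume: 30.0
  frac_maternal: 0.34
  frac_syncytio: 0.15
  frac_fetal: 0.075
  flow_maternal: 2.0
  flow_fetal: 0.2
transporters:
  V_ac: 5.0
  V_ex_mvm: 5.0
  V_ex_bm: 5.0
  V_fa: 5.0
  K_ac: 2260.0
  K_Na: 25070.0
  K_ex: 200.0
  K_fa: 1000.0
  beta: 0.33
  delta_psi: -0.021
  Na_maternal: 134000.0
  Na_syncytio: 15000.0
  z: 1.0
  F_const: 96500.0
  R_const: 8.314
  T_abs: 310.0
concentrations:
  maternal:
    AcEx: 826.0
    Ex: 170.0
    ExF: 338.0
    AcExF: 215.0
  syncytiotrophoblast:
    AcEx: 4413.0
    Ex: 786.0
    ExF: 1145.0
    AcExF: 1987.0
  fetal:
    AcEx: 1369.0
    Ex: 258.0
    ExF: 483.0
    AcExF: 238.0
inputs:
  maternal:
    AcEx: 826.0
    Ex: 170.0
    ExF: 338.0
    AcExF: 215.0
  fetal:
    AcEx: 1369.0
    Ex: 258.0
    ExF: 483.0
    AcExF: 238.0
scenario:
  name: full
  active_transporters:
  - accumulative_mvm
  - exchanger_bm
  - exchanger_mvm
  - facilitative_bm
  clamped_compartments: []
  flow_maternal_enabled: true
  flow_fetal_enabled: true
  activity_multipliers: {}
sweep: {}
fit: {}
pku: {}
output_dir: results
seed: 0
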