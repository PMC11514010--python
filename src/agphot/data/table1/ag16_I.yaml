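schema: emitter/v1
name: Ag16(I)
units:
  energy: eV
  socme: cm^-1
  rate: s^-1
  nacme: a.u.
  frequency: cm^-1
contexts:
- tag: S0-opt
  states:
  - label: T1
    energy: 1.97
  - label: T2
    energy: 2.30
  - label: S1
    energy: 2.37
    oscillator_strength: 0.91
- tag: S1-opt
  states:
  - label: T1
    energy: 1.43
  - label: S1
    energy: 1.66
    oscillator_strength: 1.27
socme_s1_t1: 2.05
supplied_rates:
  k_r: 1.54e+8
  k_isc: 8.25e+8
  k_ic: 4.96e+6
reference:
  exp_e_s1_s0opt_ev: 2.36
  exp_e_s1_s1opt_ev: 1.70
  exp_qyf_percent: 36
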