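schema: emitter/v1
name: Ag16(G)
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
    energy: 1.98
  - label: T2
    energy: 2.31
  - label: S1
    energy: 2.36
    oscillator_strength: 0.87
- tag: S1-opt
  states:
  - label: T1
    energy: 1.44
  - label: S1
    energy: 1.67
    oscillator_strength: 1.33
socme_s1_t1: 3.01
supplied_rates:
  k_r: 1.61e+8
  k_isc: 1.96e+9
  k_ic: 4.96e+6
reference:
  exp_e_s1_s0opt_ev: 2.36
  exp_e_s1_s1opt_ev: 1.68
  exp_qyf_percent: 26
  exp_k_r: 7.9e+7
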