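schema: emitter/v1
name: Ag10(I)
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
    energy: 1.95
  - label: S1
    energy: 2.57
    oscillator_strength: 0.79
- tag: S1-opt
  states:
  - label: T1
    energy: 1.78
  - label: S1
    energy: 2.17
    oscillator_strength: 1.21
socme_s1_t1: 3.68
supplied_rates:
  k_r: 2.47e+8
  k_isc: 4.85e+8
  k_ic: 1.0e+6
reference:
  exp_e_s1_s0opt_ev: 2.53
  exp_e_s1_s1opt_ev: 2.17
  exp_qyf_percent: 63
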