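schema: emitter/v1
name: Ag10(G)
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
    energy: 2.55
    oscillator_strength: 0.79
- tag: S1-opt
  states:
  - label: T1
    energy: 1.84
  - label: S1
    energy: 2.2
    oscillator_strength: 1.19
socme_s1_t1: 4.09
supplied_rates:
  k_r: 2.49e+8
  k_isc: 8.79e+8
  k_ic: 1.0e+6
reference:
  exp_e_s1_s0opt_ev: 2.53
  exp_e_s1_s1opt_ev: 2.18
  exp_qyf_percent: 25
  exp_k_r: 8.0e+8
  exp_k_isc: 5.0e+7
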