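{
  "mode": "PB",
  "_comment": "Parabolic bursting: slow activator u (gain 1/alpha_u) and slower inhibitor q oscillate beneath a Class I-like fast subsystem; burst length grows with drive (about 0.2-1.0). Time scale 10x slower than the other modes, hence the 1 ms step. Synthetic qualitative set designed with this package.",
  "phi": 2.0,
  "tau": 0.01,
  "I0": 0.0,
  "k": 0.1,
  "a_fn": 2.0,
  "b_fn": -0.5,
  "c_fn": 0.0,
  "a_fp": -2.0,
  "a_gn": 0.25,
  "b_gn": -2.0,
  "c_gn": -0.47,
  "a_gp": 4.0,
  "r_g": 0.0,
  "eps_q": 0.005,
  "a_hn": 0.25,
  "b_hn": -0.6,
  "c_hn": 0.0,
  "a_hp": 8.0,
  "r_h": -0.3,
  "eps_u": 0.04,
  "v0": 0.72,
  "alpha_u": 0.5,
  "dt": 0.001
}
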