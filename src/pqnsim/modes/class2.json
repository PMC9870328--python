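{
  "mode": "CLASS2",
  "_comment": "Hodgkin Class II: rest near a subcritical Hopf on the middle branch; graded spike amplitude and Type II (biphasic) phase-resetting curve. Synthetic qualitative set designed with this package.",
  "phi": 1.0,
  "tau": 0.001,
  "I0": -0.8225,
  "k": 1.0,
  "a_fn": 2.0,
  "b_fn": -0.5,
  "c_fn": 0.0,
  "a_fp": -2.0,
  "a_gn": 1.0,
  "b_gn": -2.0,
  "c_gn": -3.5,
  "a_gp": 4.0,
  "r_g": 0.0,
  "dt": 0.0001
}
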