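{
  "mode": "EB",
  "_comment": "Elliptic bursting: bistable (subcritical-Hopf) fast subsystem; the slow q sweeps the drive through the bistability window. Operating stimulus range about 3.8-4.4. Synthetic qualitative set designed with this package.",
  "phi": 1.0,
  "tau": 0.001,
  "I0": -0.8225,
  "k": 0.1,
  "a_fn": 2.0,
  "b_fn": -0.5,
  "c_fn": 0.0,
  "a_fp": -2.0,
  "a_gn": 1.0,
  "b_gn": -2.0,
  "c_gn": -3.5,
  "a_gp": 4.0,
  "r_g": 0.0,
  "eps_q": 0.006,
  "a_hn": 0.5,
  "b_hn": -0.35,
  "c_hn": 0.25,
  "a_hp": 6.0,
  "r_h": -0.25,
  "dt": 0.0001
}
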