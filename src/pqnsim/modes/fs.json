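{
  "mode": "FS",
  "_comment": "Fast spiking: high firing rates, weak adaptation that settles quickly after stimulus onset. Synthetic qualitative set designed with this package.",
  "phi": 3.0,
  "tau": 0.001,
  "I0": 0.0,
  "k": 1.0,
  "a_fn": 2.0,
  "b_fn": -0.5,
  "c_fn": 0.0,
  "a_fp": -2.0,
  "a_gn": 0.25,
  "b_gn": -2.0,
  "c_gn": -0.47,
  "a_gp": 4.0,
  "r_g": 0.0,
  "eps_q": 0.05,
  "a_hn": 0.25,
  "b_hn": -0.6,
  "c_hn": 0.0,
  "a_hp": 0.5,
  "r_h": -0.3,
  "dt": 0.0001
}
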