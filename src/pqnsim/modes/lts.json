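{
  "mode": "LTS",
  "_comment": "Low-threshold spiking: h is negative below rest, so hyperpolarization charges q negative and release fires a rebound burst (aided by the slow eta0 recovery while u < r_u); strong adaptation to positive steps. Synthetic qualitative set designed with this package.",
  "phi": 2.0,
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
  "eps_q": 0.003,
  "a_hn": 0.5,
  "b_hn": -1.4,
  "c_hn": -0.32,
  "a_hp": 3.0,
  "r_h": -0.3,
  "eps_u": 0.02,
  "v0": 0.6,
  "alpha_u": 1.0,
  "eta0": 0.8,
  "eta1": 1.0,
  "r_u": -0.05,
  "dt": 0.0001
}
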