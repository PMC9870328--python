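{
  "mode": "TOY3VAR",
  "_comment": "Documented toy three-variable set for testing: adds a slow h(v)=v^2 branch. Not a neuronal fit.",
  "phi": 1.0,
  "tau": 1.0,
  "I0": 0.25,
  "k": 1.0,
  "a_fn": 1.0,
  "b_fn": 0.0,
  "c_fn": 0.0,
  "a_fp": 1.0,
  "a_gn": 2.0,
  "b_gn": 0.0,
  "c_gn": 0.0,
  "a_gp": 2.0,
  "r_g": 0.0,
  "eps_q": 0.1,
  "a_hn": 1.0,
  "b_hn": 0.0,
  "c_hn": 0.0,
  "a_hp": 1.0,
  "r_h": 0.5,
  "dt": 0.0001
}
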