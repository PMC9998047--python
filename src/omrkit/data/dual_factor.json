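{
  "A": {
    "variant": "A",
    "k_f": 1,
    "k_b": 1,
    "tau_f": 0.0238,
    "k_i": 1055.42,
    "k_r": 772.934,
    "k_m": 0.034,
    "tau_m": 0.345
  },
  "B": {
    "variant": "B",
    "k_f": 291.204,
    "k_b": 0.400,
    "tau_f": 0.152,
    "k_i": 1,
    "k_r": 274.831,
    "k_m": 0.021,
    "tau_m": 0.792
  },
  "C": {
    "variant": "C",
    "k_f": 291.204,
    "k_b": 0,
    "tau_f": 0.152,
    "k_i": 1,
    "k_r": 274.831,
    "k_m": 0.021,
    "tau_m": 0.792
  }
}
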