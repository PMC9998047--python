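{
  "swim_speed_fit": {
    "variant": "single",
    "tau_f": 0.071,
    "k_i": 250.46,
    "k_r": 50092
  },
  "bout_fit": {
    "variant": "single",
    "tau_f": null,
    "k_i": 22.36,
    "k_r": 39.76
  }
}
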