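{
  "bout_rate_fit": {
    "comment": "Enhanced bout generator fitted to bout rate alone, with the intensity scale fixed per condition at the value reproducing the observed mean bout intensities.",
    "k_r": 1414.21,
    "k_m": 0.571,
    "tau_m": 0.112,
    "tau_f": null
  }
}
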