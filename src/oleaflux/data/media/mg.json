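{
  "name": "MG",
  "overrides": {
    "EX_glc": [-0.8, 1000.0],
    "EX_no3": [-1000.0, 1000.0]
  },
  "always_open": ["EX_o2", "EX_co2", "EX_h2o", "EX_h", "EX_pi", "EX_so4"]
}
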