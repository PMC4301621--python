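{
  "name": "YE",
  "overrides": {
    "EX_glc": [-0.8, 1000.0],
    "EX_no3": [-1000.0, 1000.0],
    "EX_ala": [-0.01, 1000.0],
    "EX_arg": [-0.01, 1000.0],
    "EX_asn": [-0.01, 1000.0],
    "EX_asp": [-0.01, 1000.0],
    "EX_cys": [-0.01, 1000.0],
    "EX_gln": [-0.01, 1000.0],
    "EX_glu": [-0.01, 1000.0],
    "EX_gly": [-0.01, 1000.0],
    "EX_his": [-0.01, 1000.0],
    "EX_ile": [-0.01, 1000.0],
    "EX_leu": [-0.01, 1000.0],
    "EX_lys": [-0.01, 1000.0],
    "EX_met": [-0.01, 1000.0],
    "EX_phe": [-0.01, 1000.0],
    "EX_pro": [-0.01, 1000.0],
    "EX_ser": [-0.01, 1000.0],
    "EX_thr": [-0.01, 1000.0],
    "EX_trp": [-0.01, 1000.0],
    "EX_tyr": [-0.01, 1000.0],
    "EX_val": [-0.01, 1000.0]
  },
  "always_open": ["EX_o2", "EX_co2", "EX_h2o", "EX_h", "EX_pi", "EX_so4"]
}
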