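{
  "comment": "Carbon-source exchanges for the sole-source utilization screen on the bundled synthetic model; extend this list for user models.",
  "exchanges": ["EX_glc", "EX_glyc", "EX_etoh", "EX_ac", "EX_llac", "EX_rha", "EX_orph"]
}
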