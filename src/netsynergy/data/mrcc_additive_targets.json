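{
  "Cell growth and Proliferation": [],
  "Apoptosis evasion": ["RET"],
  "Angiogenesis": ["FLT1", "KDR", "KIT", "TEK"],
  "Immune evasion": ["AXL", "FLT1", "MERTK", "TYRO3"],
  "Metastasis and Invasion": ["AXL", "NTRK2", "RET"]
}
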