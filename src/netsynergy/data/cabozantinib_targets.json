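{
  "drug_name": "cabozantinib",
  "targets": [
    {"accession": "P30530", "symbol": "AXL", "action": -1},
    {"accession": "P17948", "symbol": "FLT1", "action": -1},
    {"accession": "P36888", "symbol": "FLT3", "action": -1},
    {"accession": "P35916", "symbol": "FLT4", "action": -1},
    {"accession": "P35968", "symbol": "KDR", "action": -1},
    {"accession": "P10721", "symbol": "KIT", "action": -1},
    {"accession": "Q12866", "symbol": "MERTK", "action": -1},
    {"accession": "P08581", "symbol": "MET", "action": -1},
    {"accession": "Q16620", "symbol": "NTRK2", "action": -1},
    {"accession": "P07949", "symbol": "RET", "action": -1},
    {"accession": "P08922", "symbol": "ROS1", "action": -1},
    {"accession": "Q02763", "symbol": "TEK", "action": -1},
    {"accession": "Q06418", "symbol": "TYRO3", "action": -1}
  ]
}
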