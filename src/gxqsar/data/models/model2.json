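{
  "name": "model2",
  "cell_line": "HepG2",
  "response": "Log10 IC50 (uM)",
  "descriptors": [
    {"name": "SdssCE-index", "coefficient": -0.6407},
    {"name": "T_2_2_2", "coefficient": -0.0336},
    {"name": "H-AcceptorCount", "coefficient": -0.1278},
    {"name": "SdsCHE-index", "coefficient": 0.2226},
    {"name": "T_O_O_3", "coefficient": 0.5877}
  ],
  "intercept": 0.5940,
  "provenance": "published:model2",
  "version": 1
}
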