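{
  "name": "model1",
  "cell_line": "A549",
  "response": "Log10 IC50 (uM)",
  "descriptors": [
    {"name": "DeltaEpsilonC", "coefficient": -39.0090},
    {"name": "MMFF_29", "coefficient": -0.8078},
    {"name": "SssssCcount", "coefficient": -1.0827},
    {"name": "T_2_2_1", "coefficient": -0.0483},
    {"name": "SdsCHE-index", "coefficient": 0.5053}
  ],
  "intercept": -0.0560,
  "provenance": "published:model1",
  "version": 1
}
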