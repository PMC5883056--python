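{
  "name": "model3",
  "cell_line": "U251",
  "response": "Log10 IC50 (uM)",
  "descriptors": [
    {"name": "T_T_N_4", "coefficient": 0.0948},
    {"name": "T_O_O_3", "coefficient": 0.5217},
    {"name": "SssssCE-index", "coefficient": 0.3687}
  ],
  "intercept": 1.1313,
  "provenance": "published:model3",
  "version": 1
}
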