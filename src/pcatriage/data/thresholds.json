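{
  "risk_band": [0.05, 0.10],
  "le_band": [10.0, 15.0],
  "gain_band": [1.0, 2.0]
}
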