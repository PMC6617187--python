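{
  "description": "All-cause-mortality hazard ratios for radical treatment versus observation in localized prostate cancer, from the three long-follow-up randomized trials.",
  "effects": [
    {"source": "PIVOT", "hr": 0.84, "ci_low": 0.70, "ci_high": 1.01},
    {"source": "SPCG4", "hr": 0.74, "ci_low": 0.62, "ci_high": 0.87},
    {"source": "ProtecT", "hr": 0.93, "ci_low": 0.65, "ci_high": 1.35}
  ]
}
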