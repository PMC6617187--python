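{
  "predictor_set": [
    "psa",
    "age",
    "free_psa_pct"
  ],
  "coefficients": {
    "psa": 0.9896393798435705,
    "age": 0.033432457092769194,
    "free_psa_pct": -1.7306604791624243
  },
  "intercept": -5.473773750351682,
  "centering": {
    "psa": 2.149147554458274,
    "free_psa_pct": -2.29891005357464
  },
  "fit_metadata": {
    "n": 3616,
    "seed": 714025,
    "source": "synthetic default cohort"
  }
}
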