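{
  "cspca_shape": 1.4,
  "cspca_le_years": {
    "55-59": {
      "0": 14.5819,
      "1": 12.4511,
      "2+": 9.5855
    },
    "60-64": {
      "0": 13.3356,
      "1": 11.3853,
      "2+": 8.7601
    },
    "65-69": {
      "0": 12.3,
      "1": 10.4987,
      "2+": 8.0723
    },
    "70-74": {
      "0": 10.9,
      "1": 9.2998,
      "2+": 7.1429
    },
    "75+": {
      "0": 9.7,
      "1": 8.2715,
      "2+": 6.346
    }
  },
  "no_cspca": {
    "shape": 1.5343441522746266,
    "intercept": 3.4307545551593788,
    "coef_age": -0.04414467934801816,
    "coef_charlson_1": -0.19995719046406274,
    "coef_charlson_2plus": -0.45616198357054943,
    "age_ref": 65.0,
    "standard_errors": {
      "intercept": 0.012388670735972766,
      "coef_age": 0.0014392260891024902,
      "coef_charlson_1": 0.018810406949076517,
      "coef_charlson_2plus": 0.022968409001786348,
      "log_shape": 0.01102727759141785
    },
    "n": 19000,
    "n_events": 7217
  },
  "relative_mortality": 1.595,
  "era_effect": 0.79,
  "metadata": {
    "seed": 714025,
    "built_from": "synthetic reference cohorts"
  }
}
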