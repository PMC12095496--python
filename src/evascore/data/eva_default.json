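{
  "provenance": "package-default-synthetic",
  "intercept": 54.0,
  "coef_delta_g": 3.0,
  "coef_n_ga": 2.5,
  "coef_mit_score": 0.6,
  "coef_g17": -7.0,
  "coef_c20": -7.0,
  "clip_dg": -3.0,
  "clip_mit": 75.0,
  "n_ga_ref": 4
}
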