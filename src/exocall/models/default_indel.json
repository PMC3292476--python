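{
  "variables": [
    "nvs",
    "mean_nbq",
    "mean_variation_rate",
    "read_end_ratio"
  ],
  "intercept": -6.395831003318436,
  "coefficients": [
    2.5428770112152432,
    0.5898054589284434,
    -611.1586603326584,
    0.9104228969060418
  ],
  "platform": "synthetic",
  "provenance": "synthetic fixture training set (exocall.simulate, seed 1301); retrain on real labeled data for production use"
}
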