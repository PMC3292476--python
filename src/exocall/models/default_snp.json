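{
  "variables": [
    "ref_var_ratio",
    "strand_both",
    "mean_dist3",
    "mean_nbq",
    "mean_var_qual",
    "nbq_x_dist3",
    "strand_x_dist3"
  ],
  "intercept": -23.308556970428945,
  "coefficients": [
    -1.5169341494872755,
    1.6904341380535395,
    -0.6658430586240132,
    0.9062477111305834,
    0.3790941249092997,
    0.01083346701682162,
    0.05616143189906995
  ],
  "platform": "synthetic",
  "provenance": "synthetic fixture training set (exocall.simulate, seed 1201); retrain on real labeled data for production use"
}
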