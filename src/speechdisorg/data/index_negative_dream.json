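{
  "name": "negative_dream",
  "intercept": 30.78,
  "coefficients": {"LSC_negative": 0.015, "LSCz_negative": -2.33, "LCC_dream": -0.20},
  "source_reports": ["image_negative", "dream"],
  "provenance": "reference",
  "fit_stats": {"r_squared": 0.88, "p_value": "<0.0001", "observed_power": 1.0}
}
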