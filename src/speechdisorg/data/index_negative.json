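{
  "name": "negative",
  "intercept": 31.43,
  "coefficients": {"LCC": -0.30, "LSC": 0.08, "LSCz": -2.12},
  "source_reports": ["image_negative"],
  "provenance": "reference",
  "fit_stats": {"r_squared": 0.74, "p_value": "<0.0001", "observed_power": 0.9998}
}
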