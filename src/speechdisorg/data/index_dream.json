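{
  "name": "dream",
  "intercept": 27.82,
  "coefficients": {"LCC": -0.32, "LSC": -0.012},
  "source_reports": ["dream"],
  "provenance": "reference",
  "fit_stats": {"r_squared": 0.49, "p_value": 0.0182, "observed_power": 0.8764}
}
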