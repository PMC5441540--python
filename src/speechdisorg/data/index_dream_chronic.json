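{
  "name": "dream_chronic",
  "intercept": 93.91,
  "coefficients": {"E": -3.08, "LSC": 0.21},
  "source_reports": ["dream"],
  "provenance": "reference",
  "fit_stats": {"r_squared": 0.54, "p_value": "<0.0001", "observed_power": 1.0},
  "notes": "Estimated on a chronic-psychosis validation cohort; attributes are averages over sliding 30-word windows because that protocol was not time-limited."
}
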