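{
  "description": "Published second-order response-surface coefficients (b0..b5 on 1, X, Y, X^2, XY, Y^2) for a community ageing cohort, with X = mean-centred OEF (%) and Y = mean-centred CBF (ml/100g/min). Outcomes: log-transformed WMH volume (infarct-free subset) and the global-cognition composite Z-score. The intercept b0 was not reported and is stored as 0; axis slope/curvature combinations do not involve b0.",
  "log_wmh": {"b": [0.0, -0.86, -1.42, 0.00, 0.01, 0.01], "n": 254},
  "global_cognition": {"b": [0.0, -0.49, -0.03, 0.01, 0.00, 0.00], "n": 296}
}
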