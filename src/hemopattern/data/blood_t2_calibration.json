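{
  "description": "Haematocrit-parametrized quadratic relaxivity law mapping venous oxygen saturation Y (fraction) to blood T2: 1/T2[s^-1] = A(hct) + B(hct)*(1-Y) + C(hct)*(1-Y)^2. Representative in-vitro bovine-blood coefficients at 3 T, CPMG inter-echo spacing 10 ms; replace with an alternative calibration file to swap the law.",
  "model": "inverse_t2_quadratic_in_deoxygenation",
  "tau_cpmg_ms": 10.0,
  "A_poly_hct": [-4.4, 39.1, -33.5],
  "B_poly_hct": [1.5, 4.7],
  "C_hct_scale": 167.8,
  "valid_y_range": [0.3, 0.98]
}
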