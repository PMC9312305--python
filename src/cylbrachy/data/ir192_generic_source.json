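{
  "description": "Illustrative generic Ir-192-type HDR source parameters (synthetic, smoothed round-number tables). Editable stand-in for a commissioned source model; suitable for method development, NOT for clinical dose calculation.",
  "air_kerma_strength": 40800.0,
  "air_kerma_strength_unit": "U (uGy m^2 / h), ~10 Ci nominal",
  "dose_rate_constant": 1.109,
  "dose_rate_constant_unit": "cGy / (h U)",
  "active_length": 0.35,
  "formalism": "line",
  "radial_dose_table": [
    [0.25, 0.990],
    [0.5, 0.997],
    [1.0, 1.000],
    [1.5, 1.002],
    [2.0, 1.002],
    [3.0, 0.999],
    [4.0, 0.993],
    [5.0, 0.984],
    [6.0, 0.972],
    [8.0, 0.936],
    [10.0, 0.885]
  ],
  "anisotropy": {
    "type": "2d",
    "r_cm": [0.5, 1.0, 2.0, 3.0, 5.0],
    "theta_deg": [0, 10, 20, 30, 45, 60, 75, 90, 105, 120, 135, 150, 160, 170, 180],
    "F": [
      [0.62, 0.76, 0.86, 0.92, 0.96, 0.98, 1.00, 1.00, 1.00, 0.98, 0.96, 0.92, 0.87, 0.77, 0.64],
      [0.64, 0.78, 0.87, 0.93, 0.96, 0.99, 1.00, 1.00, 1.00, 0.99, 0.96, 0.93, 0.88, 0.79, 0.66],
      [0.67, 0.80, 0.88, 0.93, 0.97, 0.99, 1.00, 1.00, 1.00, 0.99, 0.97, 0.93, 0.89, 0.81, 0.69],
      [0.70, 0.82, 0.89, 0.94, 0.97, 0.99, 1.00, 1.00, 1.00, 0.99, 0.97, 0.94, 0.90, 0.83, 0.72],
      [0.74, 0.84, 0.90, 0.94, 0.97, 0.99, 1.00, 1.00, 1.00, 0.99, 0.97, 0.95, 0.91, 0.85, 0.76]
    ]
  }
}
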