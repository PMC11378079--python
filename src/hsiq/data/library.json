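{
  "hemoglobin_oxy": {
    "units": "mm^-1 per unit blood volume fraction",
    "note": "molar extinction compilation anchors converted assuming 150 g Hb/L whole blood, 64500 g/mol; factor 2.303*eps*(150/64500)/10"
  },
  "hemoglobin_deoxy": {
    "units": "mm^-1 per unit blood volume fraction",
    "note": "as hemoglobin_oxy, deoxygenated form"
  },
  "melanosome": {
    "units": "mm^-1 per unit melanosome volume fraction",
    "note": "power law 6.6e11 * lambda_nm^-3.33 cm^-1, sampled every 5 nm"
  },
  "water": {
    "units": "mm^-1 per unit water volume fraction",
    "note": "visible/NIR pure-water absorption compilation anchors"
  },
  "interpolation": "piecewise linear between tabulated nodes; no extrapolation"
}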