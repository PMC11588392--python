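{
  "kind": "amnion",
  "description": "Fiber-composite amnion constants; mu0 from the uniaxial calibration, the remaining constants from the source characterization.",
  "mu0": {"value": 2.4, "unit": "MPa"},
  "q": 2.96,
  "m2": 0.00228,
  "m3": 41.12,
  "m4": 1.27,
  "m5": 0.463,
  "n_fibers": 32,
  "phi": {"value": 0.0, "unit": "deg"},
  "g3_cap": 50.0
}
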