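{
  "kind": "laminate",
  "description": "Bonded trilayer bulge-test stack, loaded side first, over a 30 mm diameter aperture.",
  "aperture_radius": {"value": 15.0, "unit": "mm"},
  "layers": [
    {"name": "amnion", "material": "table1_amnion", "h0": {"value": 0.062, "unit": "mm"}},
    {"name": "chorion", "material": "table2_chorion", "h0": {"value": 0.217, "unit": "mm"}},
    {"name": "decidua", "material": "table2_decidua", "h0": {"value": 0.311, "unit": "mm"}}
  ]
}
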