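{
  "kind": "isotropic",
  "description": "Decidua small-strain elastic constants (taken equal to the chorion: the smooth chorion fuses with the decidua).",
  "E": {"value": 1.0, "unit": "MPa"},
  "nu": 0.49
}
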