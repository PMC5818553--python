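{
  "name": "high_ph",
  "description": "High external pH (8.8): acute suppression of proton-countertransporting PMCA extrusion, modeled as a constant 0.6 multiplier on pump Vmax; slows decay in all terminal types.",
  "base": "wt",
  "pump_scale": {"kind": "constant", "value": 0.6}
}
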