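{
  "name": "dnp",
  "description": "Mitochondrial uncoupling (DNP incubation): ATP-dependent clearance runs down linearly to zero over 60 min of incubation, lengthening decay times and lowering threshold frequencies.",
  "base": "wt",
  "pump_scale": {"kind": "linear_rundown", "duration_s": 3600.0}
}
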