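{
  "name": "sh_4ap",
  "description": "Shaker mutant / 4-AP block of Kv1: moderate hyperexcitability preferentially in type Is terminals, modeled as a short AP burst per stimulus.",
  "base": "wt",
  "overrides": {
    "Is": {"excitability": {"aps_per_stimulus": 3, "burst_rate": 120.0}}
  }
}
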