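{
  "name": "para_bss1",
  "description": "Hyperexcitable Na+ channel allele: burst firing per delivered stimulus combined with slow recovery from inactivation, yielding intermittent type II responses at high frequencies.",
  "base": "wt",
  "overrides": {
    "II": {"excitability": {"aps_per_stimulus": 2, "burst_rate": 120.0, "failure_recovery_time": 0.12}}
  }
}
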