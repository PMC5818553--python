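{
  "name": "para_ts1",
  "description": "Hypoexcitable Na+ channel allele: lengthened recovery from inactivation in the thin type II axon, causing conduction failures at higher stimulus frequencies (aborted / missing responses).",
  "base": "wt",
  "overrides": {
    "II": {"excitability": {"failure_recovery_time": 0.12}}
  }
}
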