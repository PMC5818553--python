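{
  "name": "tea_shab",
  "description": "TEA block / Shab RNAi: type II burst firing per stimulus and post-train rebound firing under the broad-spectrum block.",
  "base": "wt",
  "overrides": {
    "II": {"excitability": {"aps_per_stimulus": 4, "burst_rate": 120.0, "rebound_rate": 60.0, "rebound_duration": 0.4, "rebound_delay": 1.2}}
  }
}
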