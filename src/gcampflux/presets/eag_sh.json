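{
  "name": "eag_sh",
  "description": "eag Sh double perturbation (or 4-AP + quinidine): extreme hyperexcitability of type Is, with supernumerary high-frequency firing (>100 Hz burst) after every stimulus, producing single-pulse giant GCaMP responses at 2 Hz.",
  "base": "wt",
  "overrides": {
    "Is": {
      "excitability": {
        "aps_per_stimulus": 10,
        "burst_rate": 120.0
      }
    }
  }
}
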