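{
  "name": "wt",
  "description": "Wild-type control at 0.1 mM external Ca2+: one AP per stimulus, full delivery, type-specific Ca2+ influx and clearance. Clearance capacity (pump_vmax) orders Ib > Is > II and per-AP influx II > Is > Ib so that GCaMP threshold frequencies order II < Is < Ib.",
  "indicator": "GCaMP1.3",
  "pump_scale": {
    "kind": "constant",
    "value": 1.0
  },
  "notes": "ca_rest and delta_ca_per_ap are placeholders: resting Ca2+ and single-AP Ca2+ increments are not quantified for these terminals; values are tuned only to reproduce ordinal frequency-response relations and half-decay magnitudes.",
  "types": {
    "Ib": {
      "excitability": {
        "aps_per_stimulus": 1,
        "burst_rate": 100.0,
        "refractory_period": 0.002,
        "failure_recovery_time": 0.005
      },
      "calcium": {
        "ca_rest": 50.0,
        "delta_ca_per_ap": 1.6,
        "k_leak": 0.3,
        "pump_vmax": 60.0,
        "pump_km": 10.0
      }
    },
    "Is": {
      "excitability": {
        "aps_per_stimulus": 1,
        "burst_rate": 100.0,
        "refractory_period": 0.002,
        "failure_recovery_time": 0.005
      },
      "calcium": {
        "ca_rest": 50.0,
        "delta_ca_per_ap": 2.3,
        "k_leak": 0.3,
        "pump_vmax": 48.0,
        "pump_km": 15.0
      }
    },
    "II": {
      "excitability": {
        "aps_per_stimulus": 1,
        "burst_rate": 100.0,
        "refractory_period": 0.002,
        "failure_recovery_time": 0.005
      },
      "calcium": {
        "ca_rest": 50.0,
        "delta_ca_per_ap": 4.0,
        "k_leak": 0.3,
        "pump_vmax": 21.0,
        "pump_km": 30.0
      }
    }
  }
}
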