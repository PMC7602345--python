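{
  "schema_version": 1,
  "name": "untreated_25",
  "tbsa_pct": 25,
  "duration_h": 24.0,
  "treatment": {"enabled": false, "start_h": 0.0, "ketamine_mg": 0.0},
  "seed": 0
}
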