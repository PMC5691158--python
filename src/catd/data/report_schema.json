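{
  "type": "object",
  "required": [
    "seed",
    "n_samples",
    "n_targets",
    "n_calls",
    "threshold_rule",
    "thresholds",
    "samples",
    "duplicate_concordance",
    "flags",
    "config"
  ],
  "properties": {
    "seed": {"type": "integer"},
    "n_samples": {"type": "integer"},
    "n_targets": {"type": "integer"},
    "n_calls": {"type": "integer"},
    "threshold_rule": {"type": "object"},
    "thresholds": {"type": "object"},
    "samples": {"type": "object"},
    "duplicate_concordance": {"type": "object"},
    "flags": {"type": "object"},
    "config": {"type": "object"}
  }
}
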