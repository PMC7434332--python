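{
  "description": "good reporting: objective, digitization and spectral settings all present",
  "modality_hint": "spinning_disk_confocal",
  "full_expected": {
    "objective_section": "pass",
    "digitization_section": "pass",
    "spectral_section": "pass",
    "global_pass": true
  },
  "word_count_whitespace": 139
}
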