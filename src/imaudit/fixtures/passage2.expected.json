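{
  "description": "passing but incomplete: objective and digitization reported, fluorescence channel information missing",
  "modality_hint": "confocal_laser_scanning",
  "full_expected": {
    "objective_section": "pass",
    "digitization_section": "pass",
    "spectral_section": "fail",
    "global_pass": true
  },
  "word_count_whitespace": 79
}
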