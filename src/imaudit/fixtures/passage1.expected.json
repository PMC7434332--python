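{
  "description": "failing report: the confocal acquisition itself is undescribed; only the super-resolution setup carries objective and digitization detail",
  "modality_hint": "confocal_laser_scanning",
  "confocal_segment_end_marker": "Super-resolution microscopy",
  "confocal_expected": {
    "objective_section": "fail",
    "digitization_section": "fail",
    "spectral_section": "fail",
    "global_pass": false
  },
  "full_expected": {
    "objective_section": "pass",
    "digitization_section": "pass",
    "spectral_section": "fail",
    "global_pass": true
  },
  "word_count_whitespace": 123
}
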