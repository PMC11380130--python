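{
  "name": "dsr_parent_ext",
  "description": "Parenting-scenario extension of the revised Disgust Scale: 13 items scored on the 0-4 scale of the scale's first half. No subscales.",
  "n_items": 13,
  "response_range": [0, 4],
  "subscale_map": {},
  "reverse_items": []
}
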