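{
  "name": "child_22",
  "description": "22-statement child disgust-sensitivity interview; four response options counted 0-3. No default subscale map is bundled because item-to-subscale assignments are version specific; supply an edited copy of this file to enable subscales.",
  "n_items": 22,
  "response_range": [0, 3],
  "subscale_map": {},
  "reverse_items": []
}
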