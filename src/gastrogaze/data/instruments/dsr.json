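{
  "name": "dsr",
  "description": "Disgust Scale - revised, 27 items counted 0-4 (items 1-14 agree/disagree statements, 15-27 rated scenarios). The core/animal-reminder/contamination subscale map below is an externally sourced default keyed to the 27-item administration order and should be checked against the exact instrument version; reverse keying is disabled by default for the same reason.",
  "n_items": 27,
  "response_range": [0, 4],
  "subscale_map": {
    "1": "core", "3": "core", "4": "core", "5": "core", "9": "core", "11": "core",
    "13": "core", "16": "core", "19": "core", "21": "core", "23": "core", "25": "core",
    "2": "animal_reminder", "6": "animal_reminder", "8": "animal_reminder", "10": "animal_reminder",
    "14": "animal_reminder", "17": "animal_reminder", "22": "animal_reminder", "24": "animal_reminder",
    "7": "contamination", "12": "contamination", "15": "contamination", "18": "contamination",
    "20": "contamination", "26": "contamination", "27": "contamination"
  },
  "reverse_items": []
}
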