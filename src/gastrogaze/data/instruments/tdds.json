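{
  "name": "tdds",
  "description": "Three-Domain Disgust Scale: 21 items on a 7-point scale counted 0-6, equally spread over pathogen, sexual, and moral subdomains. Item keying follows the conventional interleaved order (moral 1,4,...; sexual 2,5,...; pathogen 3,6,...) and is editable.",
  "n_items": 21,
  "response_range": [0, 6],
  "subscale_map": {
    "1": "moral", "4": "moral", "7": "moral", "10": "moral", "13": "moral", "16": "moral", "19": "moral",
    "2": "sexual", "5": "sexual", "8": "sexual", "11": "sexual", "14": "sexual", "17": "sexual", "20": "sexual",
    "3": "pathogen", "6": "pathogen", "9": "pathogen", "12": "pathogen", "15": "pathogen", "18": "pathogen", "21": "pathogen"
  },
  "reverse_items": []
}
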