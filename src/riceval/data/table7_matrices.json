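{
  "criterion": {
    "labels": ["B1", "B2", "B3", "B4"],
    "matrix": [
      ["1", "3", "5", "7"],
      ["1/3", "1", "3", "5"],
      ["1/5", "1/3", "1", "3"],
      ["1/7", "1/5", "1/3", "1"]
    ]
  },
  "texture": {
    "labels": ["adhesiveness", "resilience"],
    "matrix": [
      ["1", "7"],
      ["1/7", "1"]
    ]
  }
}
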