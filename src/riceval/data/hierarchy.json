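{
  "goal": "Comprehensive quality of fresh instant rice",
  "criteria": ["B1", "B2", "B3", "B4"],
  "criterion_names": {
    "B1": "Sensory quality",
    "B2": "Texture property",
    "B3": "Color feature",
    "B4": "Physicochemical quality"
  },
  "criterion_matrix": "criterion",
  "children": {
    "B1": ["palatability"],
    "B2": ["adhesiveness", "resilience"],
    "B3": ["b_value"],
    "B4": ["iodine_color_value"]
  },
  "sub_matrices": {
    "B2": "texture"
  }
}
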