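{
  "paper_formula": {
    "palatability": 0.5650,
    "adhesiveness": 0.2294,
    "resilience": 0.0328,
    "b_value": 0.1175,
    "iodine_color_value": 0.0533
  },
  "paper_printed": {
    "palatability": 0.5650,
    "adhesiveness": 0.2294,
    "resilience": 0.0328,
    "b_value": 0.1175,
    "iodine_color_value": 0.0553
  }
}
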