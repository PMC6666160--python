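{
  "palatability": 2.83,
  "adhesiveness": -40.95,
  "resilience": 0.3,
  "b_value": 1.41,
  "iodine_color_value": 0.94
}
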