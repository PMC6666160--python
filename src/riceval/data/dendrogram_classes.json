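{
  "1": ["palatability", "taste", "sensory_comprehensive_evaluation", "appearance", "smell", "b_value"],
  "2": ["gelatinization_degree", "iodine_color_value"],
  "3": ["l_value", "a_value"],
  "4": ["chewiness", "springiness", "adhesiveness", "hardness"],
  "5": ["light_transmittance", "cohesiveness", "resilience"]
}
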