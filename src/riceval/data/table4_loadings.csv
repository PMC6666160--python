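index,f1,f2,f3,f4,f5
palatability,0.943,-0.065,0.039,-0.018,-0.041
taste,0.933,-0.090,0.051,-0.051,-0.064
sensory_comprehensive_evaluation,0.919,-0.134,0.014,-0.012,-0.109
appearance,0.890,-0.080,0.014,-0.094,0.071
smell,0.690,-0.061,0.134,-0.164,0.173
light_transmittance,-0.574,0.235,-0.057,0.084,0.053
chewiness,-0.163,0.939,0.047,0.117,0.099
springiness,0.177,0.821,0.009,0.075,-0.183
hardness,-0.275,0.762,0.071,0.009,0.238
adhesiveness,-0.272,0.647,0.096,-0.222,-0.058
l_value,0.072,0.114,0.839,0.158,0.050
a_value,-0.061,-0.042,-0.802,-0.141,0.332
b_value,0.094,0.030,0.669,-0.317,0.368
resilience,-0.171,-0.134,0.101,0.897,0.143
cohesiveness,-0.153,0.562,0.062,0.707,0.032
iodine_color_value,0.490,0.137,-0.098,0.115,0.593
gelatinization_degree,0.448,0.054,-0.041,-0.225,-0.553
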