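,l_value,a_value,b_value,iodine_color_value,light_transmittance,gelatinization_degree,hardness,adhesiveness,springiness,cohesiveness,chewiness,resilience,smell,appearance,palatability,taste,sensory_comprehensive_evaluation
l_value,,**,**,,,,,,,,,,,,,,
a_value,**,,**,,,,,,,,,,,,,,
b_value,**,**,,,,,,,,,,,,,,,
iodine_color_value,,,,,**,,,,,,,,**,**,**,**,**
light_transmittance,,,,**,,**,**,*,,*,**,,*,**,**,**,**
gelatinization_degree,,,,,**,,,,,*,,**,,**,**,**,**
hardness,,,,,**,,,**,**,**,**,,*,*,**,**,**
adhesiveness,,,,,*,,**,,**,**,**,*,,**,*,**,**
springiness,,,,,,,**,**,,**,**,,,,,,
cohesiveness,,,,,*,*,**,**,**,,**,**,**,**,*,*,*
chewiness,,,,,**,,**,**,**,**,,,,*,*,**,**
resilience,,,,,,**,,*,,**,,,,*,,*,
smell,,,,**,*,,*,,,**,,,,**,**,**,**
appearance,,,,**,**,**,*,**,,**,*,*,**,,**,**,**
palatability,,,,**,**,**,**,*,,*,*,,**,**,,**,**
taste,,,,**,**,**,**,**,,*,**,*,**,**,**,,**
sensory_comprehensive_evaluation,,,,**,**,**,**,**,,*,**,,**,**,**,**,
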