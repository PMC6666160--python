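index,min,max,mean,sd,cv
l_value,57.57,75.43,66.79,3.71,5.56
a_value,-2.5,-1.71,-2.18,0.18,-8.08
b_value,1.41,7.02,4.49,1.31,29.22
iodine_color_value,0.23,0.94,0.5,0.15,30.12
light_transmittance,37.05,91.1,55.59,10.43,18.76
gelatinization_degree,78.33,98.57,91.03,4.44,4.88
hardness,572.91,1392.48,910.52,170.34,18.71
adhesiveness,-40.95,-5.7,-19.77,6.99,-35.35
springiness,0.63,0.94,0.78,0.07,9.12
cohesiveness,0.47,0.6,0.53,0.03,5.53
chewiness,209.1,739.38,389.21,107.27,27.56
resilience,0.23,0.39,0.31,0.04,12.63
smell,-0.6,1.42,0.12,0.28,231.41
appearance,-0.92,2.35,0.37,0.54,147.65
palatability,-1.08,2.83,0.24,0.63,258.33
taste,-0.75,1.56,0.26,0.45,171.39
sensory_comprehensive_evaluation,-1.17,1.75,0.33,0.6,184.09
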