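,l_value,a_value,b_value,iodine_color_value,light_transmittance,gelatinization_degree,hardness,adhesiveness,springiness,cohesiveness,chewiness,resilience,smell,appearance,palatability,taste,sensory_comprehensive_evaluation
l_value,1.000,0.394,-0.569,0.070,-0.037,-0.050,0.093,0.117,0.144,0.178,0.140,0.157,0.135,0.040,0.096,0.049,0.047
a_value,0.394,1.000,-0.277,0.099,-0.110,0.030,0.087,0.062,-0.005,-0.054,0.031,-0.107,0.175,0.144,0.097,0.125,0.057
b_value,-0.569,-0.277,1.000,0.134,0.071,-0.069,-0.062,-0.044,-0.090,-0.088,-0.080,-0.105,-0.064,-0.030,-0.079,-0.116,-0.107
iodine_color_value,0.070,0.099,0.134,1.000,-0.295,0.067,0.033,-0.057,0.089,0.058,0.081,0.044,0.251,0.330,0.351,0.329,0.365
light_transmittance,-0.037,-0.110,0.071,-0.295,1.000,-0.313,0.319,0.207,0.132,0.228,0.287,0.158,-0.213,-0.471,-0.478,-0.490,-0.563
gelatinization_degree,-0.050,0.030,-0.069,0.067,-0.313,1.000,-0.157,-0.069,0.115,-0.211,-0.097,-0.255,0.187,0.308,0.375,0.378,0.425
hardness,0.093,0.087,-0.062,0.033,0.319,-0.157,1.000,0.405,0.379,0.392,0.893,0.044,-0.195,-0.235,-0.307,-0.344,-0.354
adhesiveness,0.117,0.062,-0.044,-0.057,0.207,-0.069,0.405,1.000,0.373,0.330,0.516,-0.198,-0.188,-0.335,-0.244,-0.250,-0.290
springiness,0.144,-0.005,-0.090,0.089,0.132,0.115,0.379,0.373,1.000,0.471,0.695,-0.138,0.066,0.064,0.086,0.090,0.028
cohesiveness,0.178,-0.054,-0.088,0.058,0.228,-0.211,0.392,0.330,0.471,1.000,0.600,0.566,-0.254,-0.252,-0.192,-0.213,-0.232
chewiness,0.140,0.031,-0.080,0.081,0.287,-0.097,0.893,0.516,0.695,0.600,1.000,0.029,-0.185,-0.195,-0.220,-0.259,-0.281
resilience,0.157,-0.107,-0.105,0.044,0.158,-0.255,0.044,-0.198,-0.138,0.566,0.029,1.000,-0.175,-0.214,-0.171,-0.196,-0.175
smell,0.135,0.175,-0.064,0.251,-0.213,0.187,-0.195,-0.188,0.066,-0.254,-0.185,-0.175,1.000,0.641,0.638,0.666,0.543
appearance,0.040,0.144,-0.030,0.330,-0.471,0.308,-0.235,-0.335,0.064,-0.252,-0.195,-0.214,0.641,1.000,0.856,0.826,0.789
palatability,0.096,0.097,-0.079,0.351,-0.478,0.375,-0.307,-0.244,0.086,-0.192,-0.220,-0.171,0.638,0.856,1.000,0.916,0.898
taste,0.049,0.125,-0.116,0.329,-0.490,0.378,-0.344,-0.250,0.090,-0.213,-0.259,-0.196,0.666,0.826,0.916,1.000,0.875
sensory_comprehensive_evaluation,0.047,0.057,-0.107,0.365,-0.563,0.425,-0.354,-0.290,0.028,-0.232,-0.281,-0.175,0.543,0.789,0.898,0.875,1.000
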