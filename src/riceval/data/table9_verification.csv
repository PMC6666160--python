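sample,palatability,adhesiveness,resilience,b_value,iodine_color_value,y_printed
Kenxiangdao 10179,0.61,-9.34,0.26,2.65,0.83,0.42
Jijing 511,1.94,-22.62,0.27,4.75,0.52,0.64
Jingyou 653,1.58,-17.42,0.28,4.36,0.51,0.56
Nanjing 46,0.70,-23.18,0.30,3.41,0.43,0.49
Ningjing 43,-0.58,-8.54,0.26,5.39,0.65,0.17
Yanjing 219,-0.42,-19.85,0.33,6.19,0.48,0.25
Jinchuan No.1,0.60,-21.39,0.28,5.13,0.52,0.43
Koshihikari (Uonuma),2.38,-36.31,0.25,4.69,0.57,0.79
Hinohikari (Hiroshima),1.41,-30.05,0.26,5.67,0.61,0.59
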