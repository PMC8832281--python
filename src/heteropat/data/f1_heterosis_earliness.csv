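cross_code,hybrid,days_to_heading_mph,days_to_heading_mph_sig,days_to_heading_bph,days_to_heading_bph_sig,plant_height_mph,plant_height_mph_sig,plant_height_bph,plant_height_bph_sig,panicles_per_plant_mph,panicles_per_plant_mph_sig,panicles_per_plant_bph,panicles_per_plant_bph_sig,gd
C330 x C373,TianfengA x Guang122,4.55,**,18.22,**,16.99,**,20.83,**,-13.31,**,-20.2,**,0.34
C330 x C205,TianfengA x Huanghuazhan-1,2.61,**,19.63,**,6.53,**,17.55,**,-10.3,ns,-22.8,**,0.3
C330 x C250,TianfengA x Huazhan,5.95,**,20.56,**,12.81,**,23.99,**,-22.59,**,-24.1,**,0.31
C330 x C375,TianfengA x Minghui63,2.50,**,24.3,**,16.00,**,30.43,**,-4.99,ns,-15.2,**,0.35
C330 x C472,TianfengA x Wushansimiao,4.56,**,17.76,**,5.71,**,21.59,**,1.24,ns,0,ns,0.29
C330 x C447,TianfengA x Huanghuazhan,10.02,**,25.7,**,7.74,**,16.92,**,-32.45,**,-35.5,**,0.24
C330 x C268,TianfengA x Minhui3301,3.02,**,27.57,**,17.26,**,31.69,**,-0.01,ns,-25.3,**,0.35
C330 x C493,TianfengA x Chenghui727,6.75,**,25.7,**,10.65,**,27.28,**,-17.30,**,-30.4,**,0.34
C330 x C492,TianfengA x Yahui2115,9.02,**,27.1,**,9.40,**,34.47,**,-26.48,**,-36.7,**,0.36
C330 x C201,TianfengA x Gui99,4.72,**,19.16,**,8.18,**,21.97,**,4.7,ns,-1.28,ns,0.34
C330 x C282,TianfengA x Yuexiangzhan,3.79,**,21.5,**,13.75,**,30.56,**,-10.24,ns,-27.9,**,0.31
C330 x C386,TianfengA x Yuenongsimiao,7.16,**,22.43,**,9.56,**,21.59,**,-0.03,ns,-17.7,**,0.27
C230 x C373,TaifengA x Guang122,-9.49,**,-2.97,**,5.39,**,7.82,**,-29.29,**,-31.9,**,0.33
C230 x C205,TaifengA x Huanghuazhan-1,-0.96,ns,9.32,ns,4.30,**,8.61,**,5.57,ns,-12.6,**,0.31
C230 x C250,TaifengA x Huazhan,-2.95,**,4.66,**,3.82,**,7.7,**,-11.66,*,-17.2,**,0.29
C230 x C375,TaifengA x Minghui63,-7.58,**,5.93,**,6.09,**,12.46,**,14.07,**,-2.31,ns,0.33
C230 x C472,TaifengA x Wushansimiao,-8.73,**,-2.54,**,0.36,ns,8.72,**,-3.57,ns,-6.9,ns,0.31
C230 x C447,TaifengA x Huanghuazhan,-0.59,ns,7.63,ns,0.66,ns,3.17,*,-8.2,ns,-16.1,**,0.24
C230 x C268,TaifengA x Minhui3301,-5.07,**,11.02,**,11.55,**,18.12,**,20.63,**,-12.6,**,0.32
C230 x C493,TaifengA x Chenghui727,-0.38,ns,11.02,ns,11.03,**,20.27,**,6.38,ns,-13.8,**,0.31
C230 x C492,TaifengA x Yahui2115,-1.34,ns,8.9,ns,3.92,**,19.93,**,-13.89,*,-28.7,**,0.33
C230 x C201,TaifengA x Gui99,-1.38,ns,6.36,ns,0.58,ns,6.91,**,-0.63,ns,-10.3,*,0.32
C230 x C282,TaifengA x Yuexiangzhan,-2.10,**,8.47,**,1.2,ns,9.4,**,28.89,**,0,ns,0.32
C230 x C386,TaifengA x Yuenongsimiao,-2.54,**,5.51,**,1.57,ns,6.34,**,-17.41,**,-34.5,**,0.29
C228 x C373,Guang8A x Guang122,2.76,**,2.2,**,8.33,**,1.99,**,-26.33,**,-33,**,0.27
C228 x C205,Guang8A x Huanghuazhan-1,-0.36,ns,1.83,*,5.65,**,5.65,**,31.30,**,14.24,**,0.23
C228 x C250,Guang8A x Huazhan,-1.47,ns,-1.47,ns,-4.04,**,-4.39,**,-39.86,**,-40.3,**,0.22
C228 x C375,Guang8A x Minghui63,-1.73,**,4.03,**,6.02,**,7.85,**,-9.37,ns,-18.2,**,0.31
C228 x C472,Guang8A x Wushansimiao,0.55,ns,1.49,ns,-1.91,ns,1.89,ns,-24.06,**,-25.9,**,0.19
C228 x C319,Guang8A x Fuhui676,5.54,**,11.72,**,7.35,**,19.88,**,-29.89,**,-39,**,0.29
C228 x C447,Guang8A x Huanghuazhan,0.73,ns,1.1,ns,3.77,**,2.2,ns,-10.05,ns,-13,*,0.22
C228 x C268,Guang8A x Minhui3301,-3.57,**,4.03,**,6.64,**,8.37,**,24.13,**,-6.51,ns,0.29
C228 x C493,Guang8A x Chenghui727,-0.89,ns,2.2,**,-0.3,ns,3.56,*,2.28,ns,-13,*,0.29
C228 x C492,Guang8A x Yahui2115,-1.43,ns,0.73,ns,3.08,**,13.81,**,-19.41,**,-29.9,**,0.33
C228 x C201,Guang8A x Gui99,0,ns,0,ns,2.26,ns,4.29,**,-15.65,**,-19.5,**,0.28
C228 x C307,Guang8A x Ce64,2.36,**,3.3,**,10.48,**,3.14,*,-25.00,**,-33.3,**,0.28
C228 x C282,Guang8A x Yuexiangzhan,-1.07,ns,1.47,ns,7.67,**,11.61,**,-15.21,*,-31.2,*,0.24
C228 x C386,Guang8A x Yuenongsimiao,2.55,**,2.93,**,3.12,**,3.66,*,-17.21,**,-31.2,**,0.21
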