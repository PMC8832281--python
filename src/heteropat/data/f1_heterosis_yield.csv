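cross_code,hybrid,grains_per_panicle_mph,grains_per_panicle_mph_sig,grains_per_panicle_bph,grains_per_panicle_bph_sig,thousand_grain_weight_mph,thousand_grain_weight_mph_sig,thousand_grain_weight_bph,thousand_grain_weight_bph_sig,grain_yield_per_plant_mph,grain_yield_per_plant_mph_sig,grain_yield_per_plant_bph,grain_yield_per_plant_bph_sig,gd
C330 x C373,TianfengA x Guang122,60.06,**,33.85,**,13.25,**,8.58,**,11.1,ns,7.88,**,0.34
C330 x C205,TianfengA x Huanghuazhan-1,23.07,**,17.79,*,-1.98,**,-9.73,**,45.34,**,22.53,**,0.3
C330 x C250,TianfengA x Huazhan,13.00,ns,12.03,ns,7.16,**,-3.61,**,-47.86,**,-43.2,**,0.31
C330 x C375,TianfengA x Minghui63,62.23,**,2.77,ns,16.40,**,14.05,**,34.61,**,25,**,0.35
C330 x C472,TianfengA x Wushansimiao,5.03,ns,4.77,ns,8.70,**,1.19,ns,52.45,**,20.2,*,0.29
C330 x C447,TianfengA x Huanghuazhan,39.58,**,32.63,**,6.57,**,-0.15,ns,21.95,*,21.01,*,0.24
C330 x C268,TianfengA x Minhui3301,50.48,**,16.73,*,18.63,**,15.14,**,20.73,*,14.7,ns,0.35
C330 x C493,TianfengA x Chenghui727,19.54,*,12.91,ns,5.99,**,-1.3,*,26.13,**,14.05,ns,0.34
C330 x C492,TianfengA x Yahui2115,29.25,**,23.98,**,6.46,**,6.33,**,4.04,ns,3.08,ns,0.36
C330 x C201,TianfengA x Gui99,-3.41,ns,-4.69,ns,2.96,**,1.99,**,-20.94,*,-30.8,**,0.34
C330 x C282,TianfengA x Yuexiangzhan,18.26,*,11.33,ns,9.18,**,2.5,**,9.25,ns,2.23,ns,0.31
C330 x C386,TianfengA x Yuenongsimiao,5.21,ns,-12.6,*,1.75,*,-4.6,**,49.39,**,32.15,**,0.27
C230 x C373,TaifengA x Guang122,37.44,**,27.57,**,7.86,**,7.28,**,60.08,**,55.22,**,0.33
C230 x C205,TaifengA x Huanghuazhan-1,18.10,*,9.78,*,-8.05,**,-18.9,**,71.19,**,44.51,**,0.31
C230 x C250,TaifengA x Huazhan,13.54,ns,2.13,ns,16.43,**,9.46,**,-11.76,ns,-20.9,**,0.29
C230 x C375,TaifengA x Minghui63,73.99,**,16.57,ns,20.37,**,17.11,**,59.01,**,37.86,**,0.33
C230 x C472,TaifengA x Wushansimiao,14.93,ns,2.82,ns,7.66,**,4.93,**,-43.67,**,-55.5,**,0.31
C230 x C447,TaifengA x Huanghuazhan,-11.34,ns,-24.3,**,6.37,**,4.39,**,23.41,**,22.64,**,0.24
C230 x C268,TaifengA x Minhui3301,60.62,**,36.71,**,20.11,**,17.98,**,10.32,ns,4.67,ns,0.32
C230 x C493,TaifengA x Chenghui727,3.54,ns,-2.5,ns,12.30,**,0.11,ns,3.47,ns,-6.31,ns,0.31
C230 x C492,TaifengA x Yahui2115,34.40,**,24.65,**,8.87,**,3.97,**,25.88,**,24.54,**,0.33
C230 x C201,TaifengA x Gui99,11.12,ns,-1.96,ns,4.61,**,-1.12,ns,94.99,**,71.03,**,0.32
C230 x C282,TaifengA x Yuexiangzhan,10.73,ns,-6.25,ns,9.61,**,7.79,**,8.01,ns,0.92,ns,0.32
C230 x C386,TaifengA x Yuenongsimiao,21.65,**,-7.58,ns,5.63,**,3.73,**,27.29,**,12.75,ns,0.29
C228 x C373,Guang8A x Guang122,43.94,**,20.37,**,2.93,**,-1.86,*,-6.54,ns,-14,ns,0.27
C228 x C205,Guang8A x Huanghuazhan-1,-6.02,ns,-10.1,ns,-4.74,**,-19,**,27.23,*,12.52,ns,0.23
C228 x C250,Guang8A x Huazhan,40.59,**,39.38,**,-0.29,ns,-2.29,**,-9.66,ns,-22.8,**,0.22
C228 x C375,Guang8A x Minghui63,74.39,**,10.48,ns,9.70,**,2.42,**,17.85,ns,15.52,ns,0.31
C228 x C472,Guang8A x Wushansimiao,8.38,ns,8.11,ns,6.29,**,4.48,**,20.84,ns,-0.52,ns,0.19
C228 x C319,Guang8A x Fuhui676,53.68,**,23.17,**,6.92,**,-0.1,ns,36.89,**,24.58,*,0.29
C228 x C447,Guang8A x Huanghuazhan,17.49,*,11.64,ns,-4.55,**,-6.82,**,41.11,**,34.5,**,0.22
C228 x C268,Guang8A x Minhui3301,15.7,ns,-10.3,ns,5.58,**,-0.53,ns,-7.18,ns,-16.3,*,0.29
C228 x C493,Guang8A x Chenghui727,12.05,ns,5.83,ns,-2.12,**,-15.9,**,41.43,**,34.77,**,0.29
C228 x C492,Guang8A x Yahui2115,51.16,**,45.01,**,1.95,*,-6.5,**,16.97,ns,9.72,ns,0.33
C228 x C201,Guang8A x Gui99,20.31,**,18.72,*,-1.90,*,-10.9,**,-1.7,ns,-9.44,ns,0.28
C228 x C307,Guang8A x Ce64,44.50,**,29.73,**,0.14,ns,-3.3,**,9.87,ns,0.74,ns,0.28
C228 x C282,Guang8A x Yuexiangzhan,13.29,ns,6.65,ns,10.98,**,8.12,**,5.67,ns,-6.08,ns,0.24
C228 x C386,Guang8A x Yuenongsimiao,21.36,**,0.81,ns,-0.01,ns,-2.46,**,77.00,**,60.33,**,0.21
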