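female,female_code,female_cluster,male,male_code,male_cluster,hybrid,gd
AnfengA,C478,IV,Yuehesimiao,C190,V,Antianyouyuehesimiao,0.351
Guang8A,C228,IV,Yuehesimiao,C190,V,Guang8youyuehesimiao,0.277
HengfengA,C227,IV,Yuehesimiao,C190,V,Hengfengyouyuehesimiao,0.290
TaifengA,C230,IV,Yuehesimiao,C190,V,Taiyouyuehesimiao,0.285
LongtepuA,C290,I,Yuehesimiao,C190,V,Teyouyuehesimiao,0.294
TianfengA,C330,IV,R122,C298,II,Tianyou122,0.341
TianfengA,C330,IV,R308,C251,V,Tianyou308,0.314
TianfengA,C330,IV,R368,C257,II,Tianyou368,0.309
TianfengA,C330,IV,R428,C245,II,Tianyou428,0.331
WufengA,C272,IV,Yuehesimiao,C190,V,Wuyouyuehesimiao,0.292
Zhenshan97B,C288,I,Minghui63,C281,II,Shanyou63,0.379
BoB,C296,I,R998,C203,II,Boyou998,0.369
Zhenshan97A,C288,I,Gui99,C536,II,ShanyouGui99,0.368
TianfengA,C330,IV,Guanghui998,C203,II,Tianyou998,0.330
WufengB,C272,IV,R998,C203,II,Wuyou998,0.325
9311B,C235,III,Huazhan,C250,V,Quanyouhuazhan,0.304
RongfengB,C219,IV,R463,C269,I,Rongyou463,0.317
Guang8A,C228,IV,Yuenongsimiao,C265,V,Guang8youyuenongsimiao,0.289
Quan9311-A,C235,III,Wushansimiao,C320,V,Quanyousimiao,0.310
TaifengB,C230,IV,R208,C248,II,RongyouTaiyou208,0.325
JifengB,C217,IV,R1002,C242,II,Jifengyou1002,0.335
TianfengB,C330,IV,Huazhan,C250,V,Tianyouhuazhan,0.308
WufengB,C272,IV,R308,C251,V,Wuyou308,0.331
WufengB,C272,IV,Huazhan,C250,V,Wuyouhuazhan,0.320
WufengB,C272,IV,Hanhui1179,C239,V,Wuyou1179,0.314
TianfengB,C330,IV,R305,C381,V,Taiyou305,0.327
TianfengB,C330,I,R398,C243,IV,Taiyou398,0.291
JifengB,C217,I,V1100,C300,IV,Jiyou1100,0.317
TeB,C290,I,R721,C303,V,Teyou721,0.315
YexiangB,C231,VI,Fuhui676,C319,II,Yexiangyou676,0.315
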