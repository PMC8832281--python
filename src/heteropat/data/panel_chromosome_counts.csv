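chromosome,n_snps
1,1345
2,1097
3,1261
4,914
5,814
6,899
7,789
8,672
9,552
10,573
11,677
12,675
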