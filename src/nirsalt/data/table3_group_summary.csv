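cohort,label,n,na_real,k_real,na_plus_k,predicted
G1,mean,310,1.99,,,1.96
G1,G11,1,2.97,,,2.75
G1,G12,1,1.21,,,1.34
G2,mean,60,0.93,1.46,2.39,1.47
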