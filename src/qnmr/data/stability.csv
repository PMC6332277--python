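time_h,purity_8.72,purity_8.45,purity_7.82
0,100.11,99.62,99.62
1,101.10,100.11,99.62
2,100.11,100.11,99.62
4,99.62,100.11,99.62
8,99.62,100.11,99.62
24,100.11,100.11,99.62
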