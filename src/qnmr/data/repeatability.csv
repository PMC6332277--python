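replicate,purity_8.72,purity_8.45,purity_7.82
1,100.71,100.71,100.19
2,100.21,100.21,100.21
3,99.70,100.21,100.21
4,99.70,99.70,100.21
5,99.70,100.21,99.70
6,99.70,100.21,100.21
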