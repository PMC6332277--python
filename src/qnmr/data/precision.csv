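replicate,m_std_mg,m_x_mg,purity_8.72,purity_8.45,purity_7.82
1,4.67,5.11,99.87,100.04,100.21
2,5.29,5.37,100.13,100.13,99.81
3,5.13,5.73,99.51,99.51,99.17
4,5.02,5.61,100.84,100.84,100.32
5,5.95,5.43,99.59,99.59,99.17
6,5.56,5.14,100.11,99.82,99.82
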