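no,in_tablets_mg,added_mg,found_8.72,found_8.45,found_7.82,recovery_8.72,recovery_8.45,recovery_7.82
1,2.51,2.00,4.48,4.53,4.48,98.60,101.04,98.60
2,2.45,1.84,4.30,4.31,4.30,100.75,101.56,100.75
3,2.54,2.02,4.53,4.54,4.51,98.50,99.17,97.50
4,2.46,2.48,4.96,5.00,4.95,101.10,102.65,100.72
5,2.50,2.59,5.11,5.12,5.04,100.71,101.16,98.04
6,2.52,2.52,4.96,4.96,5.04,96.80,96.80,99.90
7,2.52,3.00,5.60,5.54,5.44,102.65,100.66,97.26
8,2.50,2.93,5.44,5.45,5.44,100.37,100.78,100.37
9,2.52,3.01,5.58,5.61,5.48,101.60,102.54,98.38
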