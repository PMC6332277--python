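no,m_std_mg,m_x_mg,mass_ratio,area_ratio_8.72,area_ratio_8.45,area_ratio_7.82
1,5.18,2.41,0.47,0.44,0.44,0.44
2,4.83,3.45,0.71,0.67,0.67,0.67
3,5.56,5.14,0.92,0.87,0.87,0.87
4,6.46,11.72,1.81,1.68,1.68,1.67
5,5.48,14.56,2.66,2.46,2.45,2.45
6,5.00,19.40,3.88,3.64,3.64,3.64
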