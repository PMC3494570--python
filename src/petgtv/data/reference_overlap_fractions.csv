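patient,composite_cm3,common_cm3,of_ct1,of_petct1,of_sbr
1,6.95,5.02,0.72,0.91,0.96
2,47.24,46.73,0.55,0.81,1.00
3,64.82,44.56,0.59,0.93,1.00
4,95.99,99.61,0.57,1.00,1.00
5,20.35,20.82,0.45,0.81,0.91
6,2.81,2.43,0.77,0.98,1.00
7,26.16,12.89,0.61,0.85,0.90
8,66.43,50.11,0.46,1.00,1.00
9,27.64,19.48,0.67,0.96,1.00
10,105.06,97.49,0.87,0.79,0.97
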