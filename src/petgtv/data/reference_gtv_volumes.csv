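patient,gtv_ct1_cm3,gtv_ct2_cm3,gtv_petct1_cm3,gtv_petct2_cm3,gtv_sbr_cm3
1,36.06,36.04,43.28,43.26,25.4
2,60.14,54.88,34.11,27.67,18.3
3,66.43,95.06,41.69,48.84,22.0
4,2.73,4.32,1.91,1.38,1.2
5,21.48,22.72,12.19,12.33,4.6
6,95.99,96.05,86.74,70.11,67.8
7,16.99,15.10,11.23,7.59,5.4
8,6.39,4.59,3.19,2.24,1.3
9,26.41,36.45,18.21,15.44,12.7
10,103.84,106.11,78.06,98.90,54.6
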