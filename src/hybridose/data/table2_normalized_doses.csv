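patient,tumor,liver,lungs,stomach,spleen,kidneys
1,13.92,2.41,0.09,0.58,0.88,0.36
2,5.71,1.37,0.20,0.63,0.45,0.31
3,2.56,0.99,,0.26,0.36,
4,8.99,1.19,0.11,0.32,0.14,0.25
5,31.94,2.39,0.16,0.20,0.12,0.10
6,5.46,1.24,0.06,0.29,0.25,0.22
7a,3.65,1.98,0.07,0.13,0.53,0.45
7b,9.17,2.31,0.09,0.05,0.33,0.24
8,9.99,0.86,0.11,0.31,0.46,0.18
9,14.75,1.03,0.08,0.53,0.15,0.13
10,53.83,3.78,0.13,0.45,0.68,0.48
11,2.32,0.48,0.02,0.77,0.09,
12,4.76,1.69,0.17,0.20,0.73,0.17
13,162.49,7.82,0.13,0.16,0.21,
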