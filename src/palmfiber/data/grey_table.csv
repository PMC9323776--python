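k,x1_cum,x2_cum,x3_cum,x0_cum,z1
1,1.00,1.00,1.00,1.00,
2,2.02,1.81,2.10,2.56,1.78
3,3.05,2.62,3.09,3.94,3.25
4,4.12,3.50,4.07,6.10,5.02
5,5.24,4.45,4.99,8.24,7.17
6,6.47,5.34,5.84,9.93,9.09
7,7.69,6.39,6.58,12.82,11.38
8,8.90,7.50,7.39,14.37,13.60
9,9.96,8.55,8.33,15.88,15.13
10,11.29,9.60,9.03,18.82,17.35
11,12.31,10.64,10.05,20.14,19.48
12,13.52,11.63,10.75,20.61,20.37
13,14.49,12.65,11.70,22.65,21.63
14,15.66,13.80,12.54,24.75,23.70
15,16.82,15.15,13.25,26.83,25.79
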