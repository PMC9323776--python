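sample_id,cellulose,hemicellulose,lignin
1,25.63,12.79,49.12
2,28.24,10.33,50.27
3,25.44,10.35,50.31
4,25.01,11.27,52.46
5,23.56,12.18,46.33
6,21.81,11.43,60.44
7,19.06,13.39,60.01
8,57.67,13.19,20.66
9,24.14,13.42,52.28
10,17.89,13.40,65.20
11,26.36,13.35,50.16
12,17.86,12.69,59.31
13,24.39,13.07,47.55
14,21.55,14.68,57.45
15,19.56,16.26,59.97
16,18.24,17.26,58.25
17,17.20,16.88,62.24
18,17.89,17.24,59.14
19,18.19,16.10,60.30
20,17.98,17.33,58.97
21,21.83,20.96,49.49
22,26.37,11.05,38.02
23,37.93,12.23,30.82
24,8.13,13.45,76.97
25,7.93,14.43,71.06
26,80.58,14.12,3.94
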