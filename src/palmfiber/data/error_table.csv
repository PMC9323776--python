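row,predicted,actual,relative_error
1,1.18,1.56,0.24
2,1.63,1.37,0.18
3,1.91,2.17,0.12
4,1.97,2.14,0.08
5,2.14,1.69,0.26
6,1.92,2.88,0.33
7,1.72,1.56,0.10
8,1.87,1.51,0.24
9,1.67,2.94,0.43
10,1.73,1.31,0.32
11,1.93,1.47,0.31
12,2.16,1.04,1.08
13,1.99,2.10,0.05
14,1.48,2.08,0.29
15,1.18,1.56,0.24
average,,,0.29
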