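sample_id,line_equation,cs_mm_per_n,e_mpa,r2
1,ΔL/F = 0.00114 L0/A − 0.22149,-0.22149,877.19,0.81
2,ΔL/F = 7.2952 × 10^−4 L0/A + 0.14939,0.14939,1370.75,0.77
3,ΔL/F = 8.29946 × 10^−4 L0/A + 0.04912,0.04912,1204.90,0.90
4,ΔL/F = 3.44822 × 10^−4 L0/A + 0.36164,0.36164,1900.05,0.72
5,ΔL/F = 5.32816 × 10^−4 L0/A + 0.15288,0.15288,1876.82,0.95
6,ΔL/F = 6.7353 × 10^−4 L0/A + 0.26701,0.26701,1484.71,0.76
7,ΔL/F = 3.00383 × 10^−4 L0/A + 0.46724,0.46724,2529.08,0.92
8,ΔL/F = 7.32367 × 10^−4 L0/A + 1.17335,1.17335,1365.44,0.74
9,ΔL/F = 4.30302 × 10^−4 L0/A + 0.43854,0.43854,1323.95,0.78
10,ΔL/F = 3.87646 × 10^−4 L0/A + 0.69731,0.69731,2579.67,0.74
11,ΔL/F = 8.69669 × 10^−4 L0/A + 0.15684,0.15684,1149.86,0.74
12,ΔL/F = 7.73499 × 10^−4 L0/A − 0.04913,-0.04913,1292.83,0.70
13,ΔL/F = 8.98708 × 10^−4 L0/A − 0.07606,-0.07606,912.71,0.79
14,ΔL/F = 3.5204 × 10^−4 L0/A + 0.13491,0.13491,1840.59,0.86
15,ΔL/F = 5.48148 × 10^−4 L0/A + 0.21965,0.21965,1824.32,0.75
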