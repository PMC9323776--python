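sample_id,component,measured,predicted,abs_error
8,cellulose,57.67,58.88,1.21
23,cellulose,37.93,38.76,0.83
26,cellulose,80.58,78.48,2.10
8,hemicellulose,13.19,13.53,0.34
23,hemicellulose,12.23,11.83,0.4
26,hemicellulose,14.12,14.46,0.34
8,lignin,20.66,21.10,0.44
23,lignin,30.82,31.55,0.73
26,lignin,3.94,3.85,0.73
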