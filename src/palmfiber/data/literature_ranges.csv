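component,leaf_sheaths,trunks,fruit_bunch,mesocarp
cellulose,22.35 ± 0.31,44.25 ± 2.96,40.50 ± 0.37,32.00~60.00
hemicellulose,41.30 ± 2.80,33.94 ± 1.25,24.30 ± 0.14,9.80~31.00
lignin,36.35 ± 2.89,33.12 ± 2.16,35.20 ± 0.11,11.00~32.80
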