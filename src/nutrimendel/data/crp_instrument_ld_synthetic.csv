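snp_a,snp_b,r2
rs10832027,rs174547,0.031
rs1582763,rs174547,0.008
rs10521222,rs16966952,0.044
rs1558902,rs16966952,0.012
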