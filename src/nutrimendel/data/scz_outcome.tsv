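snp	chr	gene	effect_allele	other_allele	beta	se	pval	n
rs10740118	10	JMJD1C	G		0.0093	0.0110	0.399	79845
rs174547	11	FADS1	C	T	0.0205	0.0114	0.072	79845
rs16966952	16	NTAN1,PDXDC1	G	A	-0.0394	0.0117	0.001	79845
rs3798713	6	ELOVL2	C		0.0081	0.0110	0.459	79845
rs174538	11	FADS1	G	A	-0.0211	0.0117	0.072	79845
rs780094	2	GCKR	T	C	0.0007	0.0111	0.948	79845
rs3734398	6	ELOVL2	C	T	0.0088	0.0110	0.424	79845
rs2236212	6	ELOVL2	G		-0.0085	0.0110	0.439	79845
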