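pufa	snp	chr	gene	effect_allele	other_allele	beta	se	pval	n
LA	rs10740118	10	JMJD1C	G		0.248	0.043	8.08e-9	8631
LA	rs174547	11	FADS1	C	T	1.474	0.042	4.98e-274	8631
LA	rs16966952	16	NTAN1,PDXDC1	G	A	0.351	0.044	1.23e-15	8631
GLA	rs174547	11	FADS1	T	C	0.016	0.001	2.29e-72	8631
GLA	rs16966952	16	NTAN1,PDXDC1	G	A	0.006	0.001	5.0e-11	8631
DGLA	rs174547	11	FADS1	T	C	-0.350	0.010	2.63e-151	8631
DGLA	rs16966952	16	NTAN1,PDXDC1	G	A	0.220	0.020	7.55e-65	8631
AA	rs174547	11	FADS1	T	C	1.691	0.025	3.00e-971	8631
AA	rs16966952	16	NTAN1,PDXDC1	G	A	0.199	0.031	2.43e-10	8631
ALA	rs174547	11	FADS1	C	T	0.016	0.001	3.47e-64	8866
EPA	rs3798713	6	ELOVL2	C		0.035	0.005	1.93e-12	8866
EPA	rs174538	11	FADS1	G	A	0.083	0.005	5.37e-58	8866
DPA	rs780094	2	GCKR	T	C	0.017	0.003	9.04e-9	8866
DPA	rs3734398	6	ELOVL2	C	T	0.040	0.003	9.61e-44	8866
DPA	rs174547	11	FADS1	T	C	0.075	0.003	3.79e-154	8866
DHA	rs2236212	6	ELOVL2	G		0.113	0.014	1.26e-15	8866
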