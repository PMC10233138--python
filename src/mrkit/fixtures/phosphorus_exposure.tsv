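snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs1697421	1	21823292	C	T	0.49	0.050	0.005	1.14E−27	100
rs17265703	3	122048644	G	A	0.85	0.036	0.006	4.32E−09	36
rs9469578	6	33706479	T	C	0.92	0.059	0.009	1.11E−11	43
rs947583	6	136133659	T	C	0.29	0.035	0.005	3.45E−12	49
rs2970818	12	4606168	T	A	0.09	0.047	0.008	4.38E−09	35
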