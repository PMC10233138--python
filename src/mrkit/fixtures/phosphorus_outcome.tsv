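snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval
rs1697421	1	21823292	C	T	0.49	0.033	0.027	0.217
rs17265703	3	122048644	G	A	0.85	0.042	0.038	0.259
rs9469578	6	33706479	T	C	0.92	−0.021	0.052	0.684
rs947583	6	136133659	T	C	0.29	0.036	0.030	0.224
rs2970818	12	4606168	T	A	0.09	−0.029	0.044	0.510
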