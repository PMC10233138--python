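snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs2120019	15	75334184	T	C	0.79	0.287	0.033	1.60E−18	75
rs1532423	8	86268313	A	G	0.37	0.178	0.026	6.40E−12	47
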