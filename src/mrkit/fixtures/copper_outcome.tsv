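snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval
rs1175550	1	3691528	G	A	0.22	0.003	0.032	0.922
rs2769264	1	151344741	G	T	0.16	0.006	0.034	0.866
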