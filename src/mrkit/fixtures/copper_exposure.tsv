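snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs1175550	1	3691528	G	A	0.22	0.198	0.032	5.00E−10	38
rs2769264	1	151344741	G	T	0.16	0.313	0.034	2.60E−20	85
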