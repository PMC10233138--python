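snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs1800562	6	26093141	A	G	0.07	0.328	0.016	2.70E−97	696
rs1799945	6	26091179	C	G	0.15	−0.189	0.010	1.10E−81	450
rs855791	22	37462936	A	G	0.55	−0.181	0.007	1.30E−139	807
rs8177240	3	133477701	T	G	0.67	−0.066	0.007	6.70E−20	95
rs7385804	7	100235970	A	C	0.62	0.064	0.007	1.40E−18	95
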