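snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval
rs1800562	6	26093141	A	G	0.07	−0.054	0.049	0.268
rs1799945	6	26091179	C	G	0.15	0.069	0.038	0.067
rs855791	22	37462936	A	G	0.55	0.028	0.027	0.299
rs8177240	3	133477701	T	G	0.67	0.005	0.028	0.860
rs7385804	7	100235970	A	C	0.62	−0.003	0.028	0.918
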