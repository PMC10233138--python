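snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval
rs921943	5	79020653	T	C	0.29	0.069	0.029	0.019
rs567754	5	79120593	C	T	0.67	0.056	0.028	0.048
rs3797535	5	79004574	T	C	0.10	−0.011	0.049	0.816
rs11951068	5	79008491	A	G	0.06	0.076	0.051	0.137
rs705415	5	78996137	C	T	0.88	−0.008	0.042	0.841
rs6586282	21	43058387	C	T	0.85	−0.046	0.035	0.194
rs1789953	21	43062826	T	C	0.16	0.041	0.040	0.301
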