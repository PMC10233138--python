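snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs921943	5	79020653	T	C	0.29	0.250	0.020	1.90E−39	119
rs567754	5	79120593	C	T	0.67	0.170	0.020	8.40E−20	67
rs3797535	5	79004574	T	C	0.10	0.210	0.040	2.10E−15	36
rs11951068	5	79008491	A	G	0.06	0.210	0.040	1.90E−11	31
rs705415	5	78996137	C	T	0.88	0.230	0.040	4.60E−10	39
rs6586282	21	43058387	C	T	0.85	0.120	0.030	4.00E−09	21
rs1789953	21	43062826	T	C	0.16	0.120	0.030	3.40E−08	17
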