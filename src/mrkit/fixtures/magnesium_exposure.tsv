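snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	f
rs11144134	9	77499796	C	T	0.08	0.011	0.001	8.20E−15	121
rs13146355	4	77412140	A	G	0.44	0.005	0.001	6.30E−13	25
rs3925584	11	30760335	T	C	0.55	0.006	0.001	5.20E−16	36
rs4072037	1	155162067	T	C	0.54	0.010	0.001	2.00E−36	100
rs448378	3	169100899	A	G	0.53	0.004	0.001	1.30E−08	16
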