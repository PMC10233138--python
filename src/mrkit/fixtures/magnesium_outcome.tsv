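snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval
rs11144134	9	77499796	C	T	0.08	0.062	0.048	0.191
rs13146355	4	77412140	A	G	0.44	0.033	0.027	0.220
rs3925584	11	30760335	T	C	0.55	0.007	0.027	0.791
rs4072037	1	155162067	T	C	0.54	0.012	0.027	0.640
rs448378	3	169100899	A	G	0.53	0.019	0.027	0.471
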