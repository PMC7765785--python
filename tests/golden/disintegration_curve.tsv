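n_removed	lcc_size	removed_gene
0	7	
1	5	CDC42
2	3	CTNNB1
3	2	ERBB2
4	1	MAPK3
5	1	MYC
6	1	PIK3CA
7	0	RHOA
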