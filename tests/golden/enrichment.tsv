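pathway_id	pathway_name	k_overlap	set_size	p_value	p_adjusted	mean_centrality	overlap_genes	passes_filter
R-TOY-0003	MAPK cascade	3	4	0.003464166534	0.02526616876	0.8	CDC42,CTNNB1,MAPK3	1
R-TOY-0001	Rho GTPase cycle	3	5	0.008422056253	0.02526616876	0.9	CDC42,CTNNB1,ERBB2	1
R-TOY-0002	Actin cytoskeleton dynamics	3	5	0.008422056253	0.02526616876	0.9	CDC42,CTNNB1,ERBB2	1
R-TOY-0004	WNT signaling	3	5	0.008422056253	0.02526616876	0.8	CDC42,CTNNB1,MAPK3	1
R-TOY-0012	Cell cycle	2	4	0.07039567774	0.1689496266	0.7833333333	CDC42,MAPK3	0
R-TOY-0005	PI3K/AKT signaling	1	4	0.4422374066	0.7581212685	0.7	ERBB2	0
R-TOY-0008	Apoptosis	1	4	0.4422374066	0.7581212685	0.8333333333	CTNNB1	0
R-TOY-0006	Cardiac muscle contraction	0	6	1	1			0
R-TOY-0007	Glycolysis	0	3	1	1			0
R-TOY-0009	Neuronal development	0	4	1	1			0
R-TOY-0010	Acute phase response	0	4	1	1			0
R-TOY-0011	Keratinization	0	3	1	1			0
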