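pathway_id	pathway_name	cluster	leaf_rank	mean_centrality
R-TOY-0003	MAPK cascade	1	0	0.8
R-TOY-0004	WNT signaling	1	1	0.8
R-TOY-0001	Rho GTPase cycle	2	2	0.9
R-TOY-0002	Actin cytoskeleton dynamics	2	3	0.9
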