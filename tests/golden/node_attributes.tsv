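gene	betweenness	degree_centrality	combined	rank	is_key
CDC42	0.5	0.6666666667	1.166666667	0	1
CTNNB1	0.3333333333	0.5	0.8333333333	1	1
ERBB2	0.2	0.5	0.7	2	1
MAPK3	0.06666666667	0.3333333333	0.4	3	1
MYC	0.03333333333	0.3333333333	0.3666666667	4	0
PIK3CA	0	0.1666666667	0.1666666667	5	0
RHOA	0	0.1666666667	0.1666666667	6	0
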