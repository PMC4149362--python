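network	n_nodes	n_edges	avg_degree	max_degree	avg_betweenness	max_betweenness
A_ttest	406	690	3.4	47	583.42	21286.48
A_sam	121	172	2.8	21	115.23	1888.753876
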