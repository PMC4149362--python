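network	mean_degree	sd_degree	cutoff	rounded_cutoff
A_ttest	3.4	4.2	11.8	12
A_sam	2.8	2.9	8.6	9
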