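species	prior_reported	removed	added	divergent_excluded	genome_total_genes
Vv	74	5	0	0
At	105	5	3	19
Os	165	0	0	73
Ma	172	5	0	5	36542
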