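taxon_id	genome_size_bp	copies_per_genome	dna_mass_ng
Streptococcus mutans	2000000	8	3.0
Bacillus subtilis	4200000	14	3.0
Enterococcus faecalis	2900000	9	3.0
Lactobacillus gasseri	1900000	5	3.0
Staphylococcus epidermidis	2500000	6	3.0
Clostridium beijerinckii	6000000	13	3.0
Vibrio fluvialis	4800000	9	3.0
Escherichia coli	4600000	8	3.0
Pseudomonas aeruginosa	6300000	3	3.0
Parabacteroides distasonis	4800000	2	3.0
Deinococcus radiodurans	2900000	1	3.0
Cutibacterium acnes	3400000	1	3.0
Acinetobacter baumannii	3900000	1	3.0
Corynebacterium striatum	4400000	1	3.0
Bifidobacterium adolescentis	4900000	1	3.0
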