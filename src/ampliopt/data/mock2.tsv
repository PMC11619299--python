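taxon_id	genome_size_bp	copies_per_genome	dna_mass_ng
Aggregatibacter actinomycetemcomitans	2100000	6	3.0
Fusobacterium nucleatum	2200000	5	3.0
Streptococcus sanguinis	2200000	4	3.0
Porphyromonas gingivalis	2500000	2	3.0
Prevotella intermedia	2900000	2	3.0
Parvimonas micra	1900000	1	3.0
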