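# Nine region-labelled primer pairs for the synthetic 16S scaffold.
# V3-V4 is the real 341F/806R pair (806R is also V4's reverse primer);
# all other sequences are SYNTHETIC stand-ins reading the scaffold's
# conserved blocks, named only for the regions they span.
name	forward_seq	reverse_seq
V1-V2	GGCGCAGGATAAGTGTGG	CTGCAGCCCCCCGTAGG
V1-V3	GGCGCAGGATAAGTGTGG	CGAGTTGGTGGGGCAGGC
V3	CCTACGGGNGGCWGCAG	CGAGTTGGTGGGGCAGGC
V3-V4	CCTACGGGNGGCWGCAG	GGACTACHVGGGTWTCTAAT
V3-V5	CCTACGGGNGGCWGCAG	TCTGTGGCCTCTACGTTT
V4	GCCTGCCCCACCAACTCG	GGACTACHVGGGTWTCTAAT
V4-V5	GCCTGCCCCACCAACTCG	TCTGTGGCCTCTACGTTT
V5-V6	ATTAGAAACCCCGGTAGTCC	TCGTTTAGGCCCGGTCGG
V6-V8	AAACGTAGAGGCCACAGA	ACAAGATCTAACCTGGGC
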