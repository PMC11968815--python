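# NCBI translation tables.
# Columns: table_id, name, amino acids for the 64 codons in TCAG order
# (first base slowest), start/stop annotation string ('M' = initiator,
# '*' = terminator, '-' = neither) in the same codon order.
1	Standard	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	---M------**--*----M---------------M----------------------------
4	Mold/Protozoan/Mycoplasma	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	--MM------**-------M------------MMMM---------------M------------
11	Bacterial/Archaeal/Plastid	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	---M------**--*----M------------MMMM---------------M------------
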