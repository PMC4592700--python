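name	region	gene	position_bp	forward_primer	reverse_primer	dye	size_min_bp	size_max_bp
D15S118	15q14-21.1		12996879	TCAAAGACCCATATCAACCA	GTGCTGAAAAGCGACACTTA	6-FAM	218	232
D15S214	15q14-21.1	RAD51	17166170	GGAGGGCACTTCCTGAG	GCCTGGCATCACGACT	TET	260	274
D15S1006	15q14-21.1		24439646	AGGGAATACTTCAAAACTC	CCACTTGGCTATGGTGAAT	6-FAM	212	224
D17S855	17q21.31	BRCA1	37861601	GGATGGCCTTTTAGAAAGTGG	ACACAGACTTGTCCTACTGCC	6-FAM	142	156
D17S1323	17q21.31		37894900	TAGGAGATGGATTATTGGTG	AAGCAACTTTGCAATGAGTG	TET	153	161
D13S260	13q12.3-13.1	BRCA2	13503800	AGATATTGTCTCCGTTCCATGA	CCCAGATATAAGGACCTGGCTA	6-FAM	155	171
D13S290	13q12.3-13.1		12495878	CCTTAGGCCCCATAATCTT	CAAATTCCTCAATTGCAAAAT	TET	176	190
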