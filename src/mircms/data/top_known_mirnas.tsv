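mir_name	count_control	count_cms	sequence
bra-miR157	579691	253845	TTGACAGAAGATAGAGAGCAC
bra-miR168	506969	373990	TCGCTTGGTGCAGGTCGGGAC
bra-miR156	254093	231666	TTGACAGAAGAAAGAGAGCAC
bra-miR166	151210	170161	TCGGACCAGGCTTCATTCCCC
bra-miR158-5p	66094	51736	CTTTGTCTATCGTTTGGAAAAG
bra-miR158-3p	44804	34621	TTTCCAAATGTAGACAAAGCA
bra-miR5718	39028	17531	TCAGAACCAAACACAGAACAAG
bra-miR408-5p	34067	32148	ACAGGGAACAAGCAGAGCATG
bra-miR172b-3p	23598	16041	AGAATCTTGATGATGCTGCAT
bra-miR390-5p	21103	15941	AAGCTCAGGAGGGATAGCGCC
bra-miR164	15166	12237	TGGAGAAGCAGGGCACGTGCA
bra-miR165	14685	15120	TCGGACCAGGCTTCATCCCCC
bra-miR6034	12828	12514	TCTGATGTATATAGCTTTGGG
bra-miR168-3p	9015	5512	CCCGCCTTGCATCAACTGAAT
bra-miR1885	7209	8016	TACATCTTCTCCGCGGAAGCTC
bra-miR6029	6847	4093	TGGGGTTGTGATTTCAGGCTT
bra-miR160-3p	5180	4304	GCGTATGAGGAGCCATGCATA
bra-miR5654	4807	3418	ATAAATCCCAAGCATCATCCA
bra-MIR5721	4345	3606	AAAATGGAGTGGGAAATGGAG
bra-miR393-3p	4325	4780	ATCATGCGATCTCTTCGGATT
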