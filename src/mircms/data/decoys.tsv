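# Synthetic structural-RNA decoy fragments (rRNA/tRNA/sn(o)RNA/scRNA)
# used by the simulator and the annotation hierarchy; not real sequences.
category	name	sequence
rRNA	rrna-decoy-1	AGGCGTGCATGCGAAGCACAATGAGTCATAACCCTTAGACCAAAGATGAGATATGCATGAACTTATCTTCGTCCATCAATCTTGCTATACGATGGTGAAATTGGTGGGGGGCACTGCGAT
rRNA	rrna-decoy-2	CGAAGTGGCGCGGCCGACCCTAGGAAGGCATAAACTTGAGGCACGATTTGTTAGCGGGTATGCGCGTTTGGCCATGTTCCGTGGTAATTTTCCTTTTTGTGAACTTCTTGGGGGGACGAT
rRNA	rrna-decoy-3	CCACTCCCTTTGTTTACATCACGTCGCCCGCTACCACCGTAAACACTCTTCTAACGGTTCAGACGTGGAATCCATTCACTACGTCGCGTTGGGTGGGCGCCCGTCCCACTTACCCCGACC
tRNA	trna-decoy-1	GTGAGTAAGATTCATCTTTTTTCATAAGTGCATTTTCCGTGTCTAAATTGTCCATGAGGGCCTAGGACGTCTAAGCACCCTTCCA
tRNA	trna-decoy-2	AATGATAGGAGCTATTGGACCATCTAGCCCGTGCGTGGACTATTGGTGTGATCTGGACCTTTTGTGTAAACGATCCGTTAACCAA
tRNA	trna-decoy-3	TTGATCCTGCCGCACGATGCTGGCTCTCAAGGACCTTTGGGTGTGGGAACAAGATCAGGTTAATTCGGGGTAGCGCACAATGCAT
snRNA	snrna-decoy-1	TACGAGACGAGTCCTTCTCCCTGTAATGACTATTCACGAGGTGCATTCTGAAATAAATATGTACACACGCCGAGTTGGCTAGCCCCTACACCTTACAAAT
snoRNA	snorna-decoy-1	ATATTTGGGACCAGGCGACTCCAAGAGACTGGAAAAATGTCGAGGCGGAGTTGAAGGGCTGCGGGTCCCTACAGGGGCGGGCTTGGAAAA
scRNA	scrna-decoy-1	ACACGTACTCTGGCTCGACGTTCGGTTAGTGCGTACAACGCTCTTCCACAACTAAGGAGCAAACAGGGGATCCCTTCTTTACGGGGCACATCGCTCGGGCGATCAAGACC
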