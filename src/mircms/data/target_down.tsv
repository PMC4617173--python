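gene_id	rpkm_control	rpkm_cms	log2fc	fdr	annotation
Bra016846	19.369	0.001	-14.241	1.71E-72	SYP125
Bra031759	18.677	0.001	-14.189	6.8E-70	SYP125
Bra019872	12.375	0.162	-6.258	9.21E-43	SYP125
Bra015756	9.216	0.001	-13.170	3.18E-44	Serine/threonine-protein kinase
Bra008330	5.324	0.001	-12.378	2.81E-17	Pleckstrin homology (PH) domain-containing
Bra026884	2.748	0.001	-11.424	7.39E-16	Pentatricopeptide (PPR) repeat-containing
Bra035163	547.451	1.757	-8.284	0	H+-ATPase 9
Bra013168	677.150	6.843	-6.629	0	H+-ATPase 6
Bra003491	331.459	1.268	-8.030	0	VGDH2 (Vanguard 1 homolog 2)
Bra004481	1608.187	8.885	-7.500	0	Pectinesterase 5
Bra030518	19.054	0.164	-6.864	3.32E-133	Clathrin assembly protein
Bra030371	607.258	10.827	-5.810	0	Late embryogenesis abundant protein-like
Bra005178	226.835	4.629	-5.615	0	Actin 3
Bra028534	28.543	0.607	-5.555	6.96E-138	Purple acid phosphatase 21
Bra039006	2.246	0.052	-5.419	7.14E-23	Retroelement pol polyprotein
Bra022826	12.903	0.408	-4.984	2.66E-56	Triacylglycerol lipase
Bra033779	3.376	0.115	-4.882	6.72E-08	HPP integral membrane domain-containing
Bra029964	55.449	2.248	-4.624	1.35E-191	2-Oxoglutarate-Fe(II)-dependent oxygenase like
Bra005140	118.770	5.278	-4.492	0	Laccase-4
Bra001912	3.939	0.196	-4.331	1.54E-28	Alcohol oxidase-related
Bra026378	3.795	0.222	-4.097	1.68E-23	COBra-like protein 11 precursor
Bra007991	1150.764	85.857	-3.745	0	Sucrose transporter SUC1
Bra031453	1.928	0.219	-3.137	4.76E-07	Serine carboxypeptidase S10 family protein
Bra020052	14.631	2.603	-2.491	2.66E-53	Plasma membrane sulfate transporter
Bra015685	7.629	1.655	-2.205	3.7E-19	Sugar transporter
Bra036819	11.142	3.174	-1.812	2.07E-09	Putative ROP family GTPase
Bra033251	24.180	7.172	-1.753	2.46E-50	CYP86A4
Bra032722	13.487	4.457	-1.598	2.09E-25	Phosphoinositide phospholipase
Bra039028	75.548	28.242	-1.420	8.75E-108	Nucleotide-diphospho-sugar transferase like
Bra013701	3.431	1.362	-1.333	5.71E-04	F-box family protein
Bra000531	16.656	7.927	-1.071	1.35E-13	MYB81
Bra012414	24.322	11.883	-1.033	8.74E-06	Bet v I allergen family protein
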