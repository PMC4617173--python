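gene_id	rpkm_control	rpkm_cms	log2fc	fdr	annotation
Bra011781	0.153	2.406	3.980	1.13E-10	Growth-regulating factor 2J
Bra004474	0.881	8.341	3.243	1.42E-22	Galactinol synthase
Bra006956	0.420	1.767	2.073	4.46E-04	Growth-regulating factor 4
Bra017379	3.814	14.809	1.957	6.43E-16	Lysosomal thiol reductase family protein
Bra012155	3.935	14.720	1.904	2.77E-41	U-box domain-containing protein 2
Bra004363	1.826	6.322	1.791	3.02E-08	Squamosa promoter-binding protein-like 6
Bra004892	62.505	215.114	1.783	0	Transducin family protein
Bra000864	0.256	0.860	1.751	8.10E-04	Ent-copalyl diphosphate synthase
Bra027897	20.504	67.391	1.717	8.67E-123	CYP96A15
Bra028175	42.722	135.558	1.666	3.16E-147	Ribulose bisphosphate carboxylase small chain
Bra017851	0.872	2.751	1.658	3.44E-05	Growth-regulating factor 2P
Bra005019	30.610	96.012	1.649	8.96E-157	RCA (RUBISCO activase)
Bra000096	2.553	7.910	1.631	4.77E-14	Calmodulin-binding protein-like
Bra022685	1.998	5.976	1.580	5.35E-08	Cup-shaped cotyledon2
Bra029216	2.231	6.648	1.575	1.67E-07	LRR-repeat protein
Bra016937	14.438	41.059	1.508	6.99E-34	S-adenosyl-L-methionine-dependent methyltransferase
Bra017143	2.326	6.533	1.490	2.49E-15	Ceramidase family protein
Bra012263	44.469	120.598	1.439	3.82E-68	Zinc-binding family protein
Bra001369	3.402	9.054	1.412	4.47E-09	3-phosphoinositide-dependent protein kinase-1
Bra031329	37.673	98.231	1.383	8.45E-89	Cell wall-plasma membrane linker protein
Bra028181	2288.119	5965.931	1.383	0	Ribulose bisphosphate carboxylase small chain
Bra023844	5.298	13.778	1.379	5.22E-24	CRK10 (cysteine-rich rlk10)
Bra023235	89.500	228.685	1.353	2.52E-232	ATP binding / phosphoribulokinase
Bra034079	2.458	6.219	1.339	2.56E-16	Disease resistance protein
Bra030820	4.925	12.084	1.295	3.46E-10	NAC1
Bra024616	9.169	22.415	1.290	2.68E-21	Oxidoreductase
Bra030727	23.394	56.454	1.271	1.36E-51	Calreticulin-3
Bra013767	2.533	5.912	1.223	9.3E-06	Growth-regulating factor 8
Bra005131	47.935	111.401	1.217	1.35E-112	cax51
Bra030188	6.137	14.006	1.190	4.11E-06	Nudix hydrolase 25
Bra025427	1.529	3.475	1.185	2.49E-04	Brassinosteroid-6-oxidase 1
Bra036417	4.213	9.514	1.175	2.08E-17	Disease resistance protein
Bra013013	15.281	33.823	1.146	1.46E-26	Calcium sensing receptor
Bra012691	2.217	4.896	1.143	5.87E-04	2OG-Fe(II) oxygenase family protein
Bra020262	3.260	7.194	1.142	5.32E-07	TOE2 transcription factor
Bra023066	1.993	4.257	1.095	7.54E-04	Growth-regulating factor 4
Bra014184	7.485	15.606	1.060	4.65E-15	Cytochrome c biogenesis protein CCS1
Bra003311	4.714	9.724	1.045	2.85E-09	Scarecrow transcription factor
Bra040873	42.657	87.512	1.037	1.49E-64	Aminoacylase
Bra012008	3.631	7.428	1.033	1.17E-06	Cysteine/histidine-rich C1 domain-containing
Bra036135	8.977	18.315	1.029	7.59E-05	Lysosome-related
Bra011537	56.705	114.452	1.013	9.85E-94	O-Glycosyl hydrolases family 17 protein
Bra013556	3.991	8.044	1.011	7.72E-10	Homeobox-leucine zipper protein HDG2-like
Bra003518	4.133	8.286	1.004	9.55E-09	Transport inhibitor response 1
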