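mir_name	norm_control	norm_cms	log2fc	p_value	change
bra-miR157	24058.52	11589.58	-1.05	0	Down
bra-miR158-3p	494.17	79.76	-2.63	0	Down
bra-miR169	58.73	27.53	-1.09	3.62E-59	Down
bra-miR394	20.00	9.63	-1.05	4.01E-20	Down
bra-miR827	19.76	8.67	-1.19	9.70E-24	Down
bra-miR845	22.33	11.09	-1.01	7.63E-21	Down
bra-miR858	11.91	5.07	-1.23	9.91E-16	Down
bra-miR5714	1.83	0.82	-1.15	3.21E-3	Down
bra-miR5716	3.44	1.37	-1.33	5.17E-06	Down
bra-miR5718	1619.75	800.40	-1.02	0	Down
bra-miR6030	7.64	20.55	1.43	1.11E-32	Up
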