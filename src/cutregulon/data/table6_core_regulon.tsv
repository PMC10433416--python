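position	sc_dnad	sc_dna	sv_dnad	sv_dna	genes	annotation	ratio
776 415	5.53	1.17	4.19	3.44	SCO0733	Hypothetical	nd
1 518 450	5.24	1.07	3.71	2.63	SCO1422	Membrane protein	0.12
1 612 020	4.54	0.99	2.76	1.26	SCO1507	Putative VKOR protein	0.253
1 876 320	3.97	1.19	2.31	1.84	SCO1754	Putative peptidase inhibitor	0.705
2 271 015	4.10	1.26	2.14	2.38	SCO2112 SCO2113	Putative oxidase Bacterioferrin	1.009 nd
3 447 120	3.72	0.98	2.09	1.81	SCO3146	Secreted protein	1.5
3 985 875	3.98	1.11	2.06	2.00	SCO3608 SCO3609	Membrane bound serine protease Membrane protein	nd 0.486
4 064 625	5.66	1.35	4.46	4.37	SCO3681	Hypothetical protein	nd
4 379 205	4.71	0.94	2.67	2.04	SCO3977	HtrA3 protease	0.303
4 575 075	3.21	0.94	1.92	1.77	SCO4157	HtrB protease	12.60*
4 710 390	2.92	0.96	1.81	2.09	SCO4295	Putative cold shock protein	0.36
5 415 990	4.74	1.09	3.43	3.47	SCO4978 SCO4979	Integral membrane protein Phosphoenolpyruvate carboxykinase	nd nd
5 593 545	5.43	0.90	3.26	3.63	SCO5146 SCO5147	Methyltransferase ECF-subfamily sigma factor	0.409 0.449
6 025 335	4.88	0.98	3.05	2.79	SCO5530	Membrane protein	0.201
6 419 205	4.22	1.56	5.13	3.97	SCO5862-63	CutRS	na
8 072 745	4.08	0.93	2.29	2.35	SCO7261 SCO7262	Membrane protein Hypothetical protein	nd nd
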