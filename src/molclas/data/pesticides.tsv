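name	formula	vector	n_cycles	n_O	nonplanar	has_thiono_S	n_N	n_Cl	retention_time	ratio	logP	pKa	D	Dprime	is_internal_standard
Methamidophos	C2H8NO2PS	001010	0	2	1	0	1	0	2.78	0.00000	-0.779	-0.58	1.235	1.266	0
Carbendazim	C9H9N3O2	100010	2	2	0	0	3	0	6.48	1.33094	1.52	5.66	1.284	1.332	0
Thiabendazole	C10H7N3S	110010	3	0	0	0	3	0	6.91	1.48561	2.47	3.40	1.288	1.331	0
Pyrimethanil	C12H13N3	110010	2	0	0	0	3	0	10.43	2.75180	2.558	4.41	1.314	1.407	0
Cyprodinil	C14H15N3	110010	3	0	0	0	3	0	11.44	3.11511	3.012	4.22	1.344	1.470	0
TPP	C18H15O4P	111000	3	4	1	0	0	0	11.78	3.23741	4.63	-5	1.394	1.504	1
Diazinone	C12H21N2O3PS	111100	1	3	1	1	2	0	11.92	3.28777	3.766	1.21	1.398	1.509	0
Pyrazophos	C14H20N3O5PS	111110	2	5	1	1	3	0	12.24	3.40288	2.810	-1.37	1.403	1.505	0
Chlorpyrifos	C9H11NO3PSCl3	111111	1	3	1	1	1	3	13.42	3.82734	5.004	-5.28	1.394	1.494	0
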