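method	freeze_terminal_ca	generation	phase	ranked0_rmsd	lowest_energy_rmsd	opted_rmsd	lowest_rmsd
PM6D3	Y	/	Gas	1.69	1.74	1.87	1.37
B3LYP	N	/	Gas	1.63	1.65	2.55	1.38
B3LYP	N	/	Water	1.63	1.58	2.25	1.38
B3LYP	N	Boltzmann	Gas	1.56	2.05		1.28
B3LYP	N	Boltzmann	Water	1.56	1.81		1.28
B3LYP	N	Boltzmann, minimized	Gas	1.56	1.96		1.28
B3LYP	N	Boltzmann, minimized	Water	1.56	1.84		1.28
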