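method	freeze_terminal_ca	cdr	phase	ranked0_rmsd	lowest_energy_rmsd	lowest_rmsd
PM6D3	Y	H3	Gas	2.64	2.76	2.16
PM6D3	N	H3	Gas	2.53	2.67	2.03
PM6D3	N	H1, H2, H3	Gas	2.50	2.64	2.00
B3LYP	N	H3	Gas	2.66	2.87	2.30
B3LYP	N	H3	Water	2.66	2.68	2.30
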