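target_id	ranked0_ca_rmsd	md_opt_ca_rmsd	md_opt_sd
7n0r	10.92	5.62	0.97
3juy	6.37	5.71	0.23
5y80	6.61	7.59	0.47
7a4t	6.19	7.48	0.29
4nzr	6.57	7.73	0.26
6xzu	7.45	6.34	0.94
6x05	6.32	7.48	0.63
3c08	6.68	7.01	0.11
4z9k	9.04	8.01	0.37
6oca	7.61	8.01	0.34
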