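target_id	ranked0_rmsd	lowest_energy_rmsd	lowest_rmsd
4kmt	1.06	1.14	1.05
5i19	2.16	1.91	1.77
5i1l	3.80	3.20	3.19
5i17	2.86	3.71	2.86
5i1d	2.10	2.10	2.02
5i1c	2.43	1.66	1.45
5i1a	2.37	0.85	0.59
5i1i	3.72	3.51	3.51
5i15	2.16	1.94	1.35
5i16	3.19	1.70	1.39
5i18	2.88	2.88	2.88
5i1e	1.62	1.13	0.92
5i1g	2.08	2.08	2.00
5i1h	1.58	1.84	1.32
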