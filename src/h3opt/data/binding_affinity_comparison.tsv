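target_id	af2_mmgbsa	af2_mmpbsa	af2_rmsd_ca	h3opt_mmgbsa	h3opt_mmpbsa	h3opt_rmsd_ca	af2_abs_delta_mmgbsa	af2_abs_delta_mmpbsa	h3opt_abs_delta_mmgbsa	h3opt_abs_delta_mmpbsa
2ghw	-29.20	-33.36	2.7	-14.70	-21.36	3.0	8.63	2.42	23.13	14.42
2yc1	-38.85	-37.73	2.3	-43.80	-48.72	1.5	6.80	18.67	1.85	7.68
3l95	-29.59	-53.35	2.5	-47.22	-68.86	2.5	23.60	11.44	5.97	4.07
3u30	-37.31	-42.41	2.6	-44.94	-50.07	2.5	9.64	2.18	2.01	5.48
4cni	-36.96	-42.93	1.0	-31.92	-40.39	1.3	8.54	7.44	3.50	4.89
4nbz	-36.59	-43.79	1.9	-59.61	-54.23	0.6	10.17	3.30	12.85	13.74
4xnq	-13.55	-17.47	2.7	-31.51	-30.94	0.5	15.40	12.32	2.57	1.15
4ydl	-52.51	-74.25	4.8	-49.17	-73.57	3.6	6.82	6.53	10.15	7.21
5e5m	-59.72	-71.15	3.0	-41.29	-53.70	7.3	0.50	5.79	18.93	11.66
5f7y	-61.76	-69.46	2.7	-60.33	-69.43	1.4	3.95	6.38	5.38	6.41
6kyz	-12.66	-20.32	4.0	-9.36	-17.13	3.7	17.63	17.21	20.93	20.40
6o9h	-39.53	-43.45	2.8	-52.27	-57.51	0.6	10.45	13.31	2.29	0.74
6pyd	-45.87	-58.71	1.0	-35.75	-45.28	1.1	6.29	13.50	3.83	0.06
6u9s	-36.54	-48.66	1.0	-39.79	-44.80	1.3	14.35	10.42	11.11	14.28
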