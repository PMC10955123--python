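table	domain	parameter	speed	group	pre_mean	pre_sd	post_mean	post_sd	delta_pct	p	d	dif_p
1	external_rotators	ecc_mean_torque	30	intervention	30.79	7.66	34.38	9.68	11.66	0.053	0.465	0.121
1	external_rotators	ecc_mean_torque	30	control	25.95	5.72	26.27	6.65	1.27	0.777	0.101	0.121
1	external_rotators	ecc_mean_torque	60	intervention	34.91	6.85	38.02	7.48	8.91	0.022	0.593	0.330
1	external_rotators	ecc_mean_torque	60	control	28.12	5.29	30.27	8.29	7.65	0.293	0.334	0.330
1	external_rotators	ecc_peak_torque	30	intervention	39.56	9.32	45.63	11.13	15.34	0.011	0.692	0.035
1	external_rotators	ecc_peak_torque	30	control	35.63	6.28	35.93	6.10	0.84	0.777	0.088	0.035
1	external_rotators	ecc_peak_torque	60	intervention	44.06	7.64	49.31	6.77	11.92	0.002	0.950	0.253
1	external_rotators	ecc_peak_torque	60	control	37.03	7.24	40.57	7.67	9.56	0.062	0.632	0.253
1	external_rotators	con_mean_torque	30	intervention	23.24	4.56	24.47	6.49	5.29	0.152	0.286	0.394
1	external_rotators	con_mean_torque	30	control	20.10	4.55	20.81	4.77	3.53	0.341	0.302	0.394
1	external_rotators	con_mean_torque	60	intervention	26.48	5.38	27.97	6.04	5.63	0.064	0.435	0.299
1	external_rotators	con_mean_torque	60	control	22.52	4.16	23.25	4.80	3.24	0.367	0.285	0.299
1	external_rotators	con_peak_torque	30	intervention	30.98	5.98	33.31	7.51	7.52	0.077	0.404	0.145
1	external_rotators	con_peak_torque	30	control	27.38	4.40	27.55	5.37	0.62	0.835	0.064	0.145
1	external_rotators	con_peak_torque	60	intervention	34.09	6.94	36.48	6.45	7.01	0.032	0.539	0.110
1	external_rotators	con_peak_torque	60	control	29.33	4.95	29.44	5.54	0.38	0.931	0.027	0.110
1	internal_rotation_flex	active_rom	NA	intervention	69.88	6.85	70.35	10.93	0.67	0.410	0.062	0.464
1	internal_rotation_flex	active_rom	NA	control	72.46	14.11	72.68	12.93	0.30	0.451	0.038	0.464
1	internal_rotation_flex	passive_rom_sub	NA	intervention	55.91	12.84	52.59	13.30	-5.94	0.060	0.444	0.239
1	internal_rotation_flex	passive_rom_sub	NA	control	59.46	13.96	58.27	13.44	-2.00	0.590	0.168	0.239
1	internal_rotation_flex	passive_rom	NA	intervention	79.55	10.03	77.54	11.27	-2.53	0.179	0.255	0.116
1	internal_rotation_flex	passive_rom	NA	control	82.00	9.09	83.25	11.25	1.52	0.356	0.292	0.116
2	infraspinatus	fascicle_length	NA	intervention	69.47	13.31	75.23	7.82	8.29	0.038	0.632	0.031
2	infraspinatus	fascicle_length	NA	control	81.04	7.98	77.35	6.82	-4.55	0.287	0.549	0.031
2	infraspinatus	fascicle_volume	NA	intervention	273.78	79.84	291.49	48.58	6.47	0.248	0.224	0.265
2	infraspinatus	fascicle_volume	NA	control	305.05	61.38	297.60	19.73	-2.44	0.749	0.154	0.265
2	infraspinatus	fractional_anisotropy	NA	intervention	0.251	0.027	0.273	0.024	8.85	0.002	1.251	0.004
2	infraspinatus	fractional_anisotropy	NA	control	0.279	0.020	0.267	0.014	-4.33	0.307	0.523	0.004
2	supraspinatus	fascicle_length	NA	intervention	37.47	6.42	42.38	6.17	13.10	0.017	0.663	0.041
2	supraspinatus	fascicle_length	NA	control	39.99	8.00	39.59	6.45	-1.00	0.819	0.079	0.041
2	supraspinatus	fascicle_volume	NA	intervention	153.18	37.29	165.65	26.52	8.14	0.158	0.303	0.395
2	supraspinatus	fascicle_volume	NA	control	146.65	41.34	164.07	22.37	11.88	0.246	0.418	0.395
2	supraspinatus	fractional_anisotropy	NA	intervention	0.285	0.027	0.303	0.014	6.32	0.028	0.584	0.031
2	supraspinatus	fractional_anisotropy	NA	control	0.295	0.027	0.289	0.028	-1.90	0.386	0.306	0.031
3	internal_rotators	ecc_mean_torque	30	intervention	37.46	5.94	38.91	9.07	3.88	0.278	0.302	0.259
3	internal_rotators	ecc_mean_torque	30	control	31.60	6.39	31.20	7.32	1.27	0.735	0.105	0.259
3	internal_rotators	ecc_mean_torque	60	intervention	46.41	6.97	48.62	12.68	4.76	0.401	0.232	0.422
3	internal_rotators	ecc_mean_torque	60	control	37.79	5.49	39.41	9.72	4.29	0.523	0.200	0.422
3	internal_rotators	ecc_peak_torque	30	intervention	54.50	9.58	61.52	19.09	12.88	0.113	0.454	0.113
3	internal_rotators	ecc_peak_torque	30	control	45.76	11.43	46.36	10.34	1.31	0.693	0.122	0.113
3	internal_rotators	ecc_peak_torque	60	intervention	61.51	8.61	67.76	18.49	10.16	0.153	0.405	0.200
3	internal_rotators	ecc_peak_torque	60	control	52.81	9.47	54.49	13.62	3.18	0.498	0.212	0.200
3	internal_rotators	con_mean_torque	30	intervention	31.79	6.78	32.52	9.91	2.30	0.720	0.098	0.331
3	internal_rotators	con_mean_torque	30	control	27.27	7.26	26.69	6.87	2.13	0.793	0.081	0.331
3	internal_rotators	con_mean_torque	60	intervention	35.04	6.07	37.12	8.41	5.94	0.100	0.474	0.440
3	internal_rotators	con_mean_torque	60	control	29.92	5.51	31.51	8.09	5.31	0.328	0.310	0.440
3	internal_rotators	con_peak_torque	30	intervention	46.28	9.02	48.37	14.24	4.52	0.473	0.198	0.222
3	internal_rotators	con_peak_torque	30	control	39.37	9.15	38.35	8.91	-2.60	0.713	0.114	0.222
3	internal_rotators	con_peak_torque	60	intervention	47.52	7.36	52.37	12.00	10.21	0.019	0.718	0.146
3	internal_rotators	con_peak_torque	60	control	40.44	7.77	42.23	9.43	4.43	0.284	0.341	0.146
3	external_rotation_flex	active_rom	NA	intervention	104.83	7.48	107.88	9.98	2.91	0.065	0.433	0.387
3	external_rotation_flex	active_rom	NA	control	103.92	7.57	108.04	10.08	3.97	0.251	0.367	0.387
3	external_rotation_flex	passive_rom_sub	NA	intervention	78.55	6.80	81.62	8.76	3.91	0.023	0.591	0.294
3	external_rotation_flex	passive_rom_sub	NA	control	80.12	9.01	84.64	8.55	5.64	0.088	0.570	0.294
3	external_rotation_flex	passive_rom	NA	intervention	105.54	6.96	108.64	9.11	2.94	0.024	0.583	0.379
3	external_rotation_flex	passive_rom	NA	control	108.32	9.07	112.23	9.06	3.61	0.125	0.504	0.379
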