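# Built-in set of 19 amino-acid scales (one per row, AAIndex accession ids).
# Packaging note: the exact membership of this low-redundancy set is a
# packaging choice; the scales below were selected to cover hydropathy,
# hydrophilicity, polarity, size/volume, charge, flexibility, secondary
# structure propensity and surface exposure with low mutual redundancy.
# Values are the raw published values; normalization (zero mean, unit sd
# over the 20 residue types) is applied at load time by the scales module.
id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTJ820101	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPT810101	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
EISD840101	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
FAUJ830101	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
GRAR740101	0.00	2.75	1.38	0.92	0.00	0.74	0.58	0.00	0.33	0.00	0.00	1.33	0.39	0.89	0.65	1.42	0.71	0.00	0.13	0.20
GRAR740102	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
GRAR740103	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
ZIMJ680102	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
ZIMJ680104	6.00	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
CHOP780201	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOP780202	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
CHOP780203	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
FAUJ880103	1.00	2.43	2.78	3.78	5.89	0.00	4.66	4.00	4.77	4.00	4.43	2.95	2.72	3.95	6.13	1.60	2.60	3.00	8.08	6.47
CHAM820101	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
KLEP840101	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0
BHAR880101	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
FASG760101	89.09	121.15	133.10	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.20	105.09	119.12	117.15	204.23	181.19
CHOC760101	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
MCMT640101	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
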