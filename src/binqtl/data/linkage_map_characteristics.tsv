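group	n_bins	total_cm	avg_cm	gaps_lt5_pct	max_gap_cm
A01	128	84.23	0.66	97.64	13.61
A02	178	80.41	0.45	98.87	18.27
A03	240	114.82	0.48	99.58	8.48
A04	231	97.09	0.42	99.57	8.49
A05	103	110.12	1.07	95.10	6.81
A06	140	100.92	0.72	96.40	17.02
A07	137	111.1	0.81	94.85	13.28
A08	127	97.91	0.77	100.00	2.07
A09	173	90.96	0.53	98.26	19.59
A10	120	81.33	0.68	96.64	11.57
C01	155	85.23	0.55	99.35	6.38
C02	125	100.7	0.81	97.58	17.97
C03	122	106.29	0.87	97.52	15.23
C04	115	68.15	0.59	99.12	15.28
C05	169	110.94	0.66	97.62	21.7
C06	167	145.79	0.87	93.98	21.34
C07	131	77.07	0.59	97.69	17.02
C08	139	79.85	0.57	97.10	14.41
C09	99	92.3	0.93	92.86	9.62
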