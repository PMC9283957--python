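population	environment	min	max	mean	se	sd	var	kurtosis	skewness	cv_percent
RIL	2012-2013 GY	26.4	45.83	38.78	0.35	4.06	16.52	0.895	-0.883	10.47
RIL	2013-2014 QH	27.93	45.42	36.49	0.27	3.31	10.95	-0.210	0.022	9.07
RIL	2014-2015 CS	34.01	47.74	41.56	0.3	3.29	10.8	-0.592	-0.498	7.91
RIL	2015-2016 GY	25.01	42.1	36.2	0.2	2.69	7.21	1.898	-0.791	7.43
RIL	2015-2016 CS	28.72	41.71	35.53	0.24	2.72	7.4	-0.317	-0.245	7.66
RIL	2016-2017 CS	24.07	48.12	39.84	0.29	3.49	12.2	1.872	-0.589	8.76
RIL	2017-2018 TT	31.06	49.03	38.32	0.25	3.07	9.41	0.611	0.292	8.02
RIL	2017-2018 JS	21.67	46.74	38.87	0.27	3.29	10.84	4.842	-1.237	8.46
RIL	2018-2019 CS	29.94	43.52	37	0.23	2.81	7.89	-0.343	-0.123	7.59
GWAS	2014-2015 CS	32.02	50.77	42.24	0.27	3.82	14.62	-0.316	0.081	9.04
GWAS	2015-2016 CS	33.50	49.01	41.17	0.24	3.46	11.96	-0.733	0.092	8.40
GWAS	2016-2017 CS	29.24	53.39	41.53	0.32	4.53	20.53	-0.169	0.207	10.91
GWAS	BLUP	33.69	49.29	40.60	0.22	3.20	10.26	-0.286	0.547	7.88
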