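chromosome	snp_number	chromosome_length	snp_per_kb
A01	107089	23267856	4.6
A02	105683	24793737	4.26
A03	165992	29767490	5.58
A04	113531	19151660	5.93
A05	147616	23067598	6.4
A06	145427	24396386	5.96
A07	142496	24006521	5.94
A08	89148	18961941	4.7
A09	158319	33865340	4.67
A10	107570	17398227	6.18
C01	128195	38829317	3.3
C02	113683	46221804	2.46
C03	185302	60573394	3.06
C04	141790	48930237	2.9
C05	85975	43185227	1.99
C06	91498	37225952	2.46
C07	129098	44770477	2.88
C08	103876	38477087	2.7
C09	78593	48508220	1.62
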