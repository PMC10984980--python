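chr1	100000	105000	G01	0	+
chr1	200000	205000	G02	0	+
chr1	300000	305000	G03	0	+
chr1	400000	405000	G04	0	+
chr1	500000	505000	G05	0	+
chr1	600000	605000	G06	0	+
chr1	700000	705000	G07	0	+
chr1	800000	805000	G08	0	+
chr1	900000	905000	G09	0	+
chr1	1000000	1005000	G10	0	+
chr1	1100000	1105000	G11	0	+
chr1	1200000	1205000	G12	0	+
chr1	1300000	1305000	G13	0	+
chr1	1400000	1405000	G14	0	+
chr1	1500000	1505000	G15	0	+
chr1	1600000	1605000	G16	0	+
chr1	1700000	1705000	G17	0	+
chr1	1800000	1805000	G18	0	+
chr1	1900000	1905000	G19	0	+
chr1	2000000	2005000	G20	0	+
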