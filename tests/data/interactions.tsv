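bait_chrom	bait_start	bait_end	bait_genes	oe_chrom	oe_start	oe_end	score_0h	score_1h	score_10h
chr1	199000	201000	G02	chr1	149000	151000	6.2	8.0	7.5
chr1	299000	301000	G03	chr1	149000	151000	1.0	6.5	5.5
chr1	399000	401000	G04	chr1	249000	251000	2.0	6.1	5.3
chr1	499000	501000	G05	chr1	249000	251000	1.5	7.2	6.0
chr1	599000	601000	G06	chr1	349000	351000	3.1	7.0	5.5
chr1	699000	701000	G07	chr1	449000	451000	6.2	7.0	6.5
chr1	899000	901000	G09	chr1	798000	799000	6.0	6.5	6.0
chr1	999000	1001000	G10	chr1	1800000	1802000	5.5	1.0	1.0
chr1	1099000	1101000	G11	chr1	1810000	1812000	1.0	5.5	1.0
chr1	1199000	1201000	G12	chr1	1820000	1822000	1.0	1.0	5.5
chr1	1299000	1301000	G13	chr1	1830000	1832000	6.0	6.0	1.0
chr1	1399000	1401000	G14	chr1	1840000	1842000	6.0	1.0	6.0
chr1	1499000	1501000	G15	chr1	1850000	1852000	7.0	7.5	8.0
chr1	1599000	1601000	G16	chr1	1860000	1862000	0.5	4.9	5.0
chr1	99000	101000	G01	chr1	1870000	1872000	1.2	3.4	2.0
chr1	199000	201000	G02	chr1	1880000	1882000	0.3	1.1	0.9
chr1	299000	301000	G03	chr1	1890000	1892000	2.2	2.8	3.1
chr1	399000	401000	G04	chr1	1900000	1902000	4.4	4.2	3.9
chr1	499000	501000	G05	chr1	1910000	1912000	1.2	3.4	2.0
chr1	599000	601000	G06	chr1	1920000	1922000	0.3	1.1	0.9
chr1	699000	701000	G07	chr1	1930000	1932000	2.2	2.8	3.1
chr1	799000	801000	G08	chr1	1940000	1942000	4.4	4.2	3.9
chr1	899000	901000	G09	chr1	1950000	1952000	1.2	3.4	2.0
chr1	999000	1001000	G10	chr1	1960000	1962000	0.3	1.1	0.9
chr1	1099000	1101000	G11	chr1	1970000	1972000	2.2	2.8	3.1
chr1	1199000	1201000	G12	chr1	1980000	1982000	4.4	4.2	3.9
chr1	1299000	1301000	G13	chr1	1990000	1992000	1.2	3.4	2.0
chr1	1399000	1401000	G14	chr1	2000000	2002000	0.3	1.1	0.9
chr1	1499000	1501000	G15	chr1	2010000	2012000	2.2	2.8	3.1
chr1	1599000	1601000	G16	chr1	2020000	2022000	4.4	4.2	3.9
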