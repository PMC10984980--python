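site_chrom	site_start	site_end	site_class	gene	mode	time_point	distance	log2fc	primed	nearest_gene
chr1	99500	99700	promoter-bound	G01	proximal	1h	400	0.5	.	True
chr1	150000	150400	enhancer-bound	G02	distal	1h	49800	1.4	True	True
chr1	250000	250400	enhancer-bound	G04	distal	1h	149800	0.8	False	False
chr1	250000	250400	enhancer-bound	G05	distal	1h	249800	0.8	False	False
chr1	350000	350400	enhancer-bound	G06	distal	1h	249800	2	False	False
chr1	450000	450400	enhancer-bound	G07	distal	1h	249800	1	True	False
chr1	798800	799200	promoter-bound	G08	proximal	1h	1000	0.3	.	True
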