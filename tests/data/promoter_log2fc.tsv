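gene_id	log2fc
G01	0.5
G02	1.4
G03	0.2
G04	0.8
G05	0.8
G06	2.0
G07	1.0
G08	0.3
G09	0.6
G10	0.0
G11	0.0
G12	0.0
G13	0.0
G14	0.0
G15	0.0
G16	0.0
G17	0.0
G18	0.0
G19	0.0
G20	0.0
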