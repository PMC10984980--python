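chr1	149600	150800	E1
chr1	249600	250800	E2
chr1	449600	450800	E5
chr1	549900	550300	S6ac
chr1	1349800	1350800	E9
chr1	1449800	1450800	E10
chr1	1549800	1550800	E11
chr1	1749800	1750800	E13
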