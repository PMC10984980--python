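chr1	99400	99800	S1ac
chr1	149600	150800	E1
chr1	249600	250800	E2
chr1	349600	350800	E3
chr1	449600	450800	E5
chr1	797800	799100	E6
chr1	1249800	1250800	E8
chr1	1549800	1550800	E11
chr1	1649800	1650800	E12
chr1	1749800	1750800	E13
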