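chr1	449600	450800	E5
chr1	1149800	1150800	E7
chr1	1249800	1250800	E8
chr1	1449800	1450800	E10
chr1	1549800	1550800	E11
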