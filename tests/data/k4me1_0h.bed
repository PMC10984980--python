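chr1	149800	150600	E1
chr1	249800	250600	E2
chr1	349800	350600	E3
chr1	449800	450600	E5
chr1	798000	798900	E6
chr1	1150000	1150600	E7
chr1	1250000	1250600	E8
chr1	1350000	1350600	E9
chr1	1450000	1450600	E10
chr1	1550000	1550600	E11
chr1	1650000	1650600	E12
chr1	1750000	1750600	E13
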