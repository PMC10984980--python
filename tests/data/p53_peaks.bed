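chr1	99500	99700	S1
chr1	150000	150400	S2
chr1	250000	250400	S3
chr1	350000	350400	S4
chr1	450000	450400	S5
chr1	550000	550400	S6
chr1	650000	650400	S7
chr1	798800	799200	S8
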