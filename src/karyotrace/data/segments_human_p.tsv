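#chrom	start	end	CLG
chr9	0	5000000	CLG10
chr19	0	12000000	CLG10
chr1	0	5000000	CLG10
chr5	0	4000000	CLG10
chr4	0	10000000	CLG3
chr13	0	8000000	CLG3
chrX	4000000	9000000	CLG14
chr3	2000000	6000000	CLG7
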