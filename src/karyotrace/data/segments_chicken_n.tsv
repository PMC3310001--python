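#chrom	start	end	GAC
chr5	0	4000000	A1
chr2	0	4000000	A2
chr2	5000000	9000000	A3
chr4	0	5000000	C1
chr4	6000000	10000000	B0|F4
chr1	0	5000000	C2
chr3	0	4000000	A0
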