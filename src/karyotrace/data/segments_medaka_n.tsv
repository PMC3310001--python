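#chrom	start	end	GAC	3R
chr12	0	3000000	A0	a
chr8	0	3000000	A1	b
chr14	0	3000000	A1	a
chr17	0	3000000	A2	a
chr20	0	3000000	A2	b
chr9	0	3000000	A3	a
chr4	0	3000000	A3	b
chr6	0	3000000	A4	a
chr11	0	3000000	A4	b
chr2	0	3000000	A5	a
chr21	0	3000000	C1	a
chr15	0	3000000	C2	a
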