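#chrom	start	end	GAC
chr9	0	5000000	A0
chr19	0	5000000	A1
chr19	8000000	12000000	A2
chr1	0	5000000	A3
chr1	6000000	10000000	A5
chr4	0	10000000	C1
chr13	0	8000000	C2
chr5	0	4000000	A0
chr3	2000000	6000000	A4
chrX	4000000	9000000	B0|F4
chr2	0	3000000	B1
chr2	3000000	6000000	B2
chr2	6000000	9000000	B3
chr6	0	3000000	C0
chr6	3000000	6000000	C3
chr6	6000000	9000000	D0
chr7	0	3000000	D1
chr7	3000000	6000000	D2
chr7	6000000	9000000	D3
chr8	0	3000000	E0
chr8	3000000	6000000	E1
chr8	6000000	9000000	E2
chr10	0	3000000	E3
chr10	3000000	6000000	F0
chr10	6000000	9000000	F1
chr11	0	3000000	F2
chr11	3000000	6000000	F3
chr11	6000000	9000000	G0
chr12	0	3000000	G1
chr12	3000000	6000000	G2
chr12	6000000	9000000	G3
chr14	0	3000000	H0
chr14	3000000	6000000	H1
chr14	6000000	9000000	H2
chr15	0	3000000	H3
chr15	3000000	6000000	I0
chr15	6000000	9000000	I1
chr16	0	3000000	I2
chr16	3000000	6000000	J0
chr16	6000000	9000000	J1
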