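species	gene	family	chrom	start	end	strand	status
Homo_sapiens	RLN	RLN/INSL	chr9	1000000	1005000	+	gene
Homo_sapiens	INSL3	RLN/INSL	chr19	2000000	2004000	-	gene
Homo_sapiens	RLN3	RLN/INSL	chr19	10000000	10004000	+	gene
Homo_sapiens	INSL5	RLN/INSL	chr1	3000000	3004000	-	gene
Homo_sapiens	RXFP1	RXFP1/2	chr4	5000000	5080000	+	gene
Homo_sapiens	RXFP2	RXFP1/2	chr13	2000000	2060000	+	gene
Homo_sapiens	RXFP3	RXFP3/4	chr5	1500000	1503000	+	gene
Homo_sapiens	RXFP4	RXFP3/4	chr1	8000000	8003000	-	gene
Homo_sapiens	RXFP3-3	RXFP3/4	chr3	4000000	4003000	+	pseudogene
Homo_sapiens	RXFP2-like	RXFP1/2	chrX	6000000	6004000	+	pseudogene
Gallus_gallus	INSL3	RLN/INSL	chr5	1000000	1003000	+	gene
Gallus_gallus	RLN3	RLN/INSL	chr2	1500000	1503000	-	gene
Gallus_gallus	INSL5	RLN/INSL	chr2	6000000	6003000	+	gene
Gallus_gallus	RXFP1	RXFP1/2	chr4	2000000	2070000	+	gene
Gallus_gallus	RXFP2	RXFP1/2	chr4	7000000	7050000	-	gene
Gallus_gallus	RXFP2ps	RXFP1/2	chr1	1200000	1204000	+	pseudogene
Gallus_gallus	RXFP3-1	RXFP3/4	chr3	2500000	2503000	+	gene
Oryzias_latipes	rln	RLN/INSL	chr12	1000000	1003000	+	gene
Oryzias_latipes	rxfp3-1	RXFP3/4	chr12	1500000	1503000	+	gene
Oryzias_latipes	insl3	RLN/INSL	chr8	1000000	1003000	-	gene
Oryzias_latipes	rxfp3-2b	RXFP3/4	chr8	1600000	1603000	+	gene
Oryzias_latipes	rxfp3-2a	RXFP3/4	chr14	1000000	1003000	+	gene
Oryzias_latipes	rln3a	RLN/INSL	chr17	1000000	1003000	+	gene
Oryzias_latipes	rln3b	RLN/INSL	chr20	1000000	1003000	-	gene
Oryzias_latipes	insl5a	RLN/INSL	chr9	1000000	1003000	+	gene
Oryzias_latipes	insl5b	RLN/INSL	chr4	1000000	1003000	+	gene
Oryzias_latipes	rxfp3-3a1	RXFP3/4	chr6	1000000	1003000	+	gene
Oryzias_latipes	rxfp3-3a2	RXFP3/4	chr6	1050000	1053000	+	gene
Oryzias_latipes	rxfp3-3b	RXFP3/4	chr11	1000000	1003000	-	gene
Oryzias_latipes	rxfp4	RXFP3/4	chr2	1000000	1003000	+	gene
Oryzias_latipes	rxfp1	RXFP1/2	chr21	1000000	1060000	+	gene
Oryzias_latipes	rxfp2	RXFP1/2	chr15	1000000	1055000	-	gene
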