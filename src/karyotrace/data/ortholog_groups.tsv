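group	species	gene
RLN	Homo_sapiens	RLN
RLN	Oryzias_latipes	rln
INSL3	Homo_sapiens	INSL3
INSL3	Gallus_gallus	INSL3
INSL3	Oryzias_latipes	insl3
RLN3	Homo_sapiens	RLN3
RLN3	Gallus_gallus	RLN3
RLN3	Oryzias_latipes	rln3a
RLN3	Oryzias_latipes	rln3b
INSL5	Homo_sapiens	INSL5
INSL5	Gallus_gallus	INSL5
INSL5	Oryzias_latipes	insl5a
INSL5	Oryzias_latipes	insl5b
RXFP1	Homo_sapiens	RXFP1
RXFP1	Gallus_gallus	RXFP1
RXFP1	Oryzias_latipes	rxfp1
RXFP2	Homo_sapiens	RXFP2
RXFP2	Gallus_gallus	RXFP2
RXFP2	Gallus_gallus	RXFP2ps
RXFP2	Oryzias_latipes	rxfp2
RXFP3-1	Homo_sapiens	RXFP3
RXFP3-1	Gallus_gallus	RXFP3-1
RXFP3-1	Oryzias_latipes	rxfp3-1
RXFP3-2	Oryzias_latipes	rxfp3-2a
RXFP3-2	Oryzias_latipes	rxfp3-2b
RXFP3-3	Homo_sapiens	RXFP3-3
RXFP3-3	Oryzias_latipes	rxfp3-3a1
RXFP3-3	Oryzias_latipes	rxfp3-3a2
RXFP3-3	Oryzias_latipes	rxfp3-3b
RXFP3-4	Homo_sapiens	RXFP4
RXFP3-4	Oryzias_latipes	rxfp4
RXFP2-like	Homo_sapiens	RXFP2-like
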