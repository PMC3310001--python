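species	chrom	rank	gene	family
Gallus_gallus	chr4	110	CENPI	CENPI
Gallus_gallus	chr4	111	DLG3	DLG3
Gallus_gallus	chr4	112	IGBP1	IGBP1
Gallus_gallus	chr4	113	EDA	EDA
Gallus_gallus	chr4	114	HEPH	HEPH
Gallus_gallus	chr4	115	MSN	MSN
Gallus_gallus	chr4	116	ARHGEF9	ARHGEF9
Gallus_gallus	chr4	117	YIPF6	YIPF6
Gallus_gallus	chr4	118	OPHN1	OPHN1
Gallus_gallus	chr4	119	STARD8	STARD8
Gallus_gallus	chr4	120	RXFP2	RXFP1/2
Gallus_gallus	chr4	121	EFNB1	EFNB1
Gallus_gallus	chr4	122	PJA1	PJA1
Gallus_gallus	chr4	123	FAM155B	FAM155B
Gallus_gallus	chr4	124	TIMM8A	TIMM8A
Gallus_gallus	chr4	125	BTK	BTK
Gallus_gallus	chr4	126	GLA	GLA
Gallus_gallus	chr4	127	HNRNPH2	HNRNPH2
Gallus_gallus	chr4	128	ARMCX1	ARMCX1
Gallus_gallus	chr4	129	NONO	NONO
Gallus_gallus	chr4	130	ITGB1BP2	ITGB1BP2
Homo_sapiens	chrX	77	ITGB1BP2	ITGB1BP2
Homo_sapiens	chrX	78	NONO	NONO
Homo_sapiens	chrX	79	ARMCX1	ARMCX1
Homo_sapiens	chrX	80	HNRNPH2	HNRNPH2
Homo_sapiens	chrX	81	GLA	GLA
Homo_sapiens	chrX	82	BTK	BTK
Homo_sapiens	chrX	83	TIMM8A	TIMM8A
Homo_sapiens	chrX	84	FAM155B	FAM155B
Homo_sapiens	chrX	85	PJA1	PJA1
Homo_sapiens	chrX	86	EFNB1	EFNB1
Homo_sapiens	chrX	87	RXFP2-like	RXFP1/2
Homo_sapiens	chrX	88	STARD8	STARD8
Homo_sapiens	chrX	89	OPHN1	OPHN1
Homo_sapiens	chrX	90	YIPF6	YIPF6
Homo_sapiens	chrX	91	ARHGEF9	ARHGEF9
Homo_sapiens	chrX	92	MSN	MSN
Homo_sapiens	chrX	93	HEPH	HEPH
Homo_sapiens	chrX	94	EDA	EDA
Homo_sapiens	chrX	95	IGBP1	IGBP1
Homo_sapiens	chrX	96	DLG3	DLG3
Homo_sapiens	chrX	97	CENPI	CENPI
Homo_sapiens	chr13	30	MIPEP	MIPEP
Homo_sapiens	chr13	31	SGCG	SGCG
Homo_sapiens	chr13	32	SACS	SACS
Homo_sapiens	chr13	33	TNFRSF19	TNFRSF19
Homo_sapiens	chr13	34	SHISA2	SHISA2
Homo_sapiens	chr13	35	N4BP2L1	N4BP2L1
Homo_sapiens	chr13	36	N4BP2L2	N4BP2L2
Homo_sapiens	chr13	37	PDS5B	PDS5B
Homo_sapiens	chr13	38	BRCA2	BRCA2
Homo_sapiens	chr13	39	FRY	FRY
Homo_sapiens	chr13	40	RXFP2	RXFP1/2
Homo_sapiens	chr13	41	LHFP	LHFP
Homo_sapiens	chr13	42	COG6	COG6
Homo_sapiens	chr13	43	FOXO1	FOXO1
Homo_sapiens	chr13	44	MRPS31	MRPS31
Homo_sapiens	chr13	45	SLC25A15	SLC25A15
Homo_sapiens	chr13	46	ELF1	ELF1
Homo_sapiens	chr13	47	WBP4	WBP4
Homo_sapiens	chr13	48	KBTBD6	KBTBD6
Homo_sapiens	chr13	49	KBTBD7	KBTBD7
Homo_sapiens	chr13	50	MTRF1	MTRF1
Homo_sapiens	chr2	0	BGA000	BGA000
Homo_sapiens	chr2	1	BGA001	BGA001
Homo_sapiens	chr2	2	BGA002	BGA002
Homo_sapiens	chr2	3	BGA003	BGA003
Homo_sapiens	chr2	4	BGA004	BGA004
Homo_sapiens	chr2	5	BGA005	BGA005
Homo_sapiens	chr2	6	BGA006	BGA006
Homo_sapiens	chr2	7	BGA007	BGA007
Homo_sapiens	chr2	8	BGA008	BGA008
Homo_sapiens	chr2	9	BGA009	BGA009
Homo_sapiens	chr2	10	BGA010	BGA010
Homo_sapiens	chr2	11	BGA011	BGA011
Homo_sapiens	chr2	12	BGA012	BGA012
Homo_sapiens	chr2	13	BGA013	BGA013
Homo_sapiens	chr2	14	BGA014	BGA014
Homo_sapiens	chr2	15	BGA015	BGA015
Homo_sapiens	chr2	16	BGA016	BGA016
Homo_sapiens	chr2	17	BGA017	BGA017
Homo_sapiens	chr2	18	BGA018	BGA018
Homo_sapiens	chr2	19	BGA019	BGA019
Homo_sapiens	chr2	20	BGA020	BGA020
Homo_sapiens	chr2	21	BGA021	BGA021
Homo_sapiens	chr2	22	BGA022	BGA022
Homo_sapiens	chr2	23	BGA023	BGA023
Homo_sapiens	chr2	24	BGA024	BGA024
Homo_sapiens	chr2	25	BGA025	BGA025
Homo_sapiens	chr2	26	BGA026	BGA026
Homo_sapiens	chr2	27	BGA027	BGA027
Homo_sapiens	chr2	28	BGA028	BGA028
Homo_sapiens	chr2	29	BGA029	BGA029
Homo_sapiens	chr2	30	BGA030	BGA030
Homo_sapiens	chr2	31	BGA031	BGA031
Homo_sapiens	chr2	32	BGA032	BGA032
Homo_sapiens	chr2	33	BGA033	BGA033
Homo_sapiens	chr2	34	BGA034	BGA034
Homo_sapiens	chr2	35	BGA035	BGA035
Homo_sapiens	chr2	36	BGA036	BGA036
Homo_sapiens	chr2	37	BGA037	BGA037
Homo_sapiens	chr2	38	BGA038	BGA038
Homo_sapiens	chr2	39	BGA039	BGA039
Homo_sapiens	chr2	40	BGA040	BGA040
Homo_sapiens	chr2	41	BGA041	BGA041
Homo_sapiens	chr2	42	BGA042	BGA042
Homo_sapiens	chr2	43	BGA043	BGA043
Homo_sapiens	chr2	44	BGA044	BGA044
Homo_sapiens	chr2	45	BGA045	BGA045
Homo_sapiens	chr2	46	BGA046	BGA046
Homo_sapiens	chr2	47	BGA047	BGA047
Homo_sapiens	chr2	48	BGA048	BGA048
Homo_sapiens	chr2	49	BGA049	BGA049
Homo_sapiens	chr2	50	BGA050	BGA050
Homo_sapiens	chr2	51	BGA051	BGA051
Homo_sapiens	chr2	52	BGA052	BGA052
Homo_sapiens	chr2	53	BGA053	BGA053
Homo_sapiens	chr2	54	BGA054	BGA054
Homo_sapiens	chr2	55	BGA055	BGA055
Homo_sapiens	chr2	56	BGA056	BGA056
Homo_sapiens	chr2	57	BGA057	BGA057
Homo_sapiens	chr2	58	BGA058	BGA058
Homo_sapiens	chr2	59	BGA059	BGA059
Homo_sapiens	chr7	0	BGB000	BGB000
Homo_sapiens	chr7	1	BGB001	BGB001
Homo_sapiens	chr7	2	BGB002	BGB002
Homo_sapiens	chr7	3	BGB003	BGB003
Homo_sapiens	chr7	4	BGB004	BGB004
Homo_sapiens	chr7	5	BGB005	BGB005
Homo_sapiens	chr7	6	BGB006	BGB006
Homo_sapiens	chr7	7	BGB007	BGB007
Homo_sapiens	chr7	8	BGB008	BGB008
Homo_sapiens	chr7	9	BGB009	BGB009
Homo_sapiens	chr7	10	BGB010	BGB010
Homo_sapiens	chr7	11	BGB011	BGB011
Homo_sapiens	chr7	12	BGB012	BGB012
Homo_sapiens	chr7	13	BGB013	BGB013
Homo_sapiens	chr7	14	BGB014	BGB014
Homo_sapiens	chr7	15	BGB015	BGB015
Homo_sapiens	chr7	16	BGB016	BGB016
Homo_sapiens	chr7	17	BGB017	BGB017
Homo_sapiens	chr7	18	BGB018	BGB018
Homo_sapiens	chr7	19	BGB019	BGB019
Homo_sapiens	chr7	20	BGB020	BGB020
Homo_sapiens	chr7	21	BGB021	BGB021
Homo_sapiens	chr7	22	BGB022	BGB022
Homo_sapiens	chr7	23	BGB023	BGB023
Homo_sapiens	chr7	24	BGB024	BGB024
Homo_sapiens	chr7	25	BGB025	BGB025
Homo_sapiens	chr7	26	BGB026	BGB026
Homo_sapiens	chr7	27	BGB027	BGB027
Homo_sapiens	chr7	28	BGB028	BGB028
Homo_sapiens	chr7	29	BGB029	BGB029
Homo_sapiens	chr7	30	BGB030	BGB030
Homo_sapiens	chr7	31	BGB031	BGB031
Homo_sapiens	chr7	32	BGB032	BGB032
Homo_sapiens	chr7	33	BGB033	BGB033
Homo_sapiens	chr7	34	BGB034	BGB034
Homo_sapiens	chr7	35	BGB035	BGB035
Homo_sapiens	chr7	36	BGB036	BGB036
Homo_sapiens	chr7	37	BGB037	BGB037
Homo_sapiens	chr7	38	BGB038	BGB038
Homo_sapiens	chr7	39	BGB039	BGB039
Homo_sapiens	chr7	40	BGB040	BGB040
Homo_sapiens	chr7	41	BGB041	BGB041
Homo_sapiens	chr7	42	BGB042	BGB042
Homo_sapiens	chr7	43	BGB043	BGB043
Homo_sapiens	chr7	44	BGB044	BGB044
Homo_sapiens	chr7	45	BGB045	BGB045
Homo_sapiens	chr7	46	BGB046	BGB046
Homo_sapiens	chr7	47	BGB047	BGB047
Homo_sapiens	chr7	48	BGB048	BGB048
Homo_sapiens	chr7	49	BGB049	BGB049
Homo_sapiens	chr7	50	BGB050	BGB050
Homo_sapiens	chr7	51	BGB051	BGB051
Homo_sapiens	chr7	52	BGB052	BGB052
Homo_sapiens	chr7	53	BGB053	BGB053
Homo_sapiens	chr7	54	BGB054	BGB054
Homo_sapiens	chr7	55	BGB055	BGB055
Homo_sapiens	chr7	56	BGB056	BGB056
Homo_sapiens	chr7	57	BGB057	BGB057
Homo_sapiens	chr7	58	BGB058	BGB058
Homo_sapiens	chr7	59	BGB059	BGB059
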