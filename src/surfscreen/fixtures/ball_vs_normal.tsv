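rank	probe_id	symbol	canonical	score
1	209795_at	CD69	CD69	90.8
2	221349_at	VPREB1	VPREB1	83.3
3	34210_at	CD52	CD52	57.3
4	212827_at	IGHM	IGHM	53.9
5	217028_at	CXCR4	CXCR4	44.3
6	206660_at	IGGL1	IGLL1	43.1
7	208650_s_at	CD24	CD24	39.7
8	220068_at	VPREB3	VPREB3	35.4
9	207857_at	LILRA2	LILRA2	34.9
10	211742_s_at	EVI2B	EVI2B	27.7
11	203434_s_at	MME	MME	26.9
12	204897_at	PTGER4	PTGER4	26.7
13	213416_at	ITGA4	ITGA4	23.4
14	205049_s_at	CD79A	CD79A	22.0
15	205297_s_at	CD79B	CD79B	21.7
16	209732_at	CLEC2B	CLEC2B	18.1
17	209267_s_at	SLC39A8	SLC39A8	16.9
18	206398_s_at	CD19	CD19	16.7
19a	208894_at	HLA-DRA	HLA-DRA	16.7
20	206247_at	MICB	MICB	16.7
21	238488_at	LRRC70	LRRC70	14.7
19b	212671_s_at	HLA-DQ1	HLA-DQ1	14.2
22	225622_at	PAG1	PAG1	14.2
23	210146_x_at	LILRB2	LILRB2	13.0
24	211744_s_at	CD58	CD58	12.8
25	204192_at	CD37	CD37	12.3
26	208302_at	HMHB1	HMHB1	12.3
27	206674_at	FLT3	FLT3	11.1
28	215925_s_at	CD72	CD72	10.4
29	203416_at	CD53	CD53	10.3
30	223533_at	LRR8C	LRRC8C	10.2
19c	211991_s_at	HLA-DPA1	HLA-DPA1	10.1
31	221601_s_at	FAIM3	FAIM3	9.8
32	226017_at	CMTM7	CMTM7	9.7
33	210176_at	TLR1	TLR1	9.6
34	228592_at	MS4A1	MS4A1	9.5
35	214181_x_at	LST1	LST1	9.1
19d	217478_s_at	HLA-DMA	HLA-DMA	9.1
36	213674_x_at	IGHD	IGHD	8.7
37	217947_at	CMTM6	CMTM6	8.4
38	237510_at	CD97	CD97	8.3
39	212873_at	MHMA1	HMHA1	8.1
40	217513_at	MILR1	MILR1	7.9
41	204949_at	ICAM-3	ICAM3	7.9
42	204563_at	SELL	SELL	7.7
43	231124_x_at	LY9	LY9	7.5
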