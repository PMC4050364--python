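rank	probe_id	symbol	canonical	score
1a	211796_s_at	TCRBV5-4	TCRBV5-4	97.6
2	213539_at	CD3D	CD3D	67.5
3	204897_at	PTGER4	PTGER4	64.9
4	209795_at	CD69	CD69	60.8
1b	210915_x_at	TRBC1	TRBC1	56.7
1c	213193_x_at	TCBC1/BV19	TCBC1/BV19	48.9
5	213416_at	ITGA4	ITGA4	39.4
6	34210_at	CD52	CD52	36.7
7	215784_at	CD1E	CD1E	35.3
1d	216191_s_at	TCRDC	TRDC	28.6
8	204563_at	SELL	SELL	26.1
9	206545_at	CD28	CD28	25.6
10	217028_at	CXCR4	CXCR4	24.6
11	211742_s_at	EVI2B	EVI2B	23.1
12	209267_s_at	SLC39A8	SLC39A8	20.9
13	204949_at	ICAM-3/CD50	ICAM3	20.2
14	212588_at	PTPRC	PTPRC	19.6
15	206761_at	CD96	CD96	17.1
16	214551_s_at	CD7	CD7	16.4
17	1554240_a_at	ITGAL/CD11a	ITGAL	15.3
18	206247_at	MICB	MICB	14.4
19	238488_at	LRRC70	LRRC70	13.0
20	205831_at	CD2	CD2	13.0
21	205456_at	CD3E	CD3E	12.6
1e	213060_s_at	TCRG2	TCRG2	12.4
22	209732_at	CLEC2B	CLEC2B	12.2
23	210031_at	CD247	CD247	11.6
24	204116_at	IL2RG	IL2RG	11.4
1f	213830_at	TCR delta	TRD	11.2
25	206749_at	CD1B	CD1B	11.0
26	206804_at	CD3G	CD3G	11.0
27	229686_at	P2RY8	P2RY8	10.6
28	207165_at	HMMR	HMMR	10.4
29	204192_at	CD37	CD37	10.2
30	201028_s_at	CD99	CD99	10.2
31	1556037_s_at	HHIP	HHIP	10.2
32	226218_at	IL-7R	IL7R	8.5
33	214181_x_at	LST1	LST1	8.5
34	204960_at	PTPRCAP	PTPRCAP	8.3
35	212873_at	HMHA1	HMHA1	7.8
36	218589_at	LPAR6	LPAR6	7.5
37	217529_at	ORAI2	ORAI2	7.1
1g	211144_x_at	TCRGC 2	TCRGC2	7.0
38	244352_at	CD84	CD84	6.9
39	215442_s_at	TSHR	TSHR	6.8
40	217947_at	CMTM6	CMTM6	6.8
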