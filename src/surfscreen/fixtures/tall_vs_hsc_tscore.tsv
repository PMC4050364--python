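rank	probe_id	symbol	canonical	score
1		CD3D	CD3D	50.7
2		CD3G	CD3G	24.2
3		TRBC1	TRBC1	22.1
4		CD99	CD99	20.8
5		CD7	CD7	20.1
6		B2M	B2M	18.6
7		CD96	CD96	17.2
8		IL2RG	IL2RG	17.0
9		CD3E	CD3E	16.9
10		LIME1	LIME1	16.1
11		CD46	CD46	16.1
12		CD247	CD247	16.0
13		ITGB1	ITGB1	14.3
14		LAX1	LAX1	13.5
15		ITGAE	ITGAE	13.4
16		HHIP	HHIP	12.9
17		ITM2A	ITM2A	12.4
18		CXCR4	CXCR4	12.2
19		CD28	CD28	12.1
20		IGHM	IGHM	12.1
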