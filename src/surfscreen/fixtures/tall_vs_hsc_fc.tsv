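rank	probe_id	symbol	canonical	score
1		CD3D	CD3D	140.1
2		TRBC1	TRBC1	110.7
3		CD1E	CD1E	54.6
4		TRDC	TRDC	42.9
5		TRDV3	TRDV3	39.4
6		CD2	CD2	39.2
7		CD28	CD28	31
8		CD3E	CD3E	28.6
9		CD7	CD7	26.6
10		CD1B	CD1B	26
11		HHIP	HHIP	23.3
12		CD96	CD96	22.9
13		CD99	CD99	22.1
14		CD3G	CD3G	21.2
15		AQP3	AQP3	20.7
16		IL-7R	IL7R	20.5
17		LPAR6	LPAR6	18.5
18		CD8A	CD8A	18.5
19		IL2RG	IL2RG	18.1
20		PVRIG	PVRIG	16.4
21		TSPAN7	TSPAN7	16.1
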