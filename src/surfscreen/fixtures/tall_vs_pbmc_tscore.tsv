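rank	probe_id	symbol	canonical	score
1		TFRC	TFRC	21.2
2		TSPAN7	TSPAN7	19.8
3		TBXA2R	TBXA2R	19.5
4		CD3D	CD3D	19.4
5		FAF1	FAF1	16.4
6		HHIP	HHIP	14.6
7		SLC39A8	SLC39A8	14.5
8		A1BG	A1BG	14.2
9		OTOP2	OTOP2	13.4
10		ITGAE	ITGAE	13.3
11		TMEM237	TMEM237	12.9
12		TRO	TRO	12.6
13		SLC22A7	SLC22A7	12.5
14		SLC7A5	SLC7A5	12.2
15		CACFD1	CACFD1	11.8
16		IGH	IGH	11.1
17		TNFRSF21	TNFRSF21	11
18		VANGL1	VANGL1	10.8
19		FGFR1	FGFR1	10.6
20		GPC2	GPC2	10.6
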