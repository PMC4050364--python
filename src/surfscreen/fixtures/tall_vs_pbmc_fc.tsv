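rank	probe_id	symbol	canonical	score
1		TSPAN7	TSPAN7	55.0
2		HHIP	HHIP	23.7
3		HMMR	HMMR	12.8
4		IGSF10	IGSF10	11.4
5		VANGL1	VANGL1	6.8
6		TFRC	TFRC	5.3
7		TRO	TRO	5.0
8		CACNB3	CACNB3	4.3
9		MAGED1	MAGED1	4.2
10		CD3D	CD3D	4.1
11		CHRNA5	CHRNA5	4.1
12		FAF1	FAF1	3.1
13		PTK7	PTK7	3.1
14		A1BG	A1BG	2.8
15		GPC2	GPC2	2.4
16		LRRC37A3	LRRC37A3	2.2
17		IGH	IGH	2.2
18		MRC2	MRC2	2.1
19		SCNN1A	SCNN1A	2.1
20		LGR4	LGR4	1.9
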