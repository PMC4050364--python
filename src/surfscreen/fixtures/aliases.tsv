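alias	canonical
CD62L	SELL
MHMA1	HMHA1
ICAM-3	ICAM3
ICAM-3/CD50	ICAM3
TCRDC	TRDC
TCR delta	TRD
TCRGC 2	TCRGC2
ITGAL/CD11a	ITGAL
IL-7R	IL7R
IGGL1	IGLL1
LRR8C	LRRC8C
CLELC2B	CLEC2B
TALLA-1	TSPAN7
CD49d	ITGA4
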