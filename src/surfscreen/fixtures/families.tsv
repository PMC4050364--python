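canonical	family
TCRBV5-4	TCR_chain
TRBC1	TCR_chain
TCBC1/BV19	TCR_chain
TRDC	TCR_chain
TCRG2	TCR_chain
TRD	TCR_chain
TCRGC2	TCR_chain
TRDV3	TCR_chain
TRBC2	TCR_chain
CD3D	CD3_complex
CD3E	CD3_complex
CD3G	CD3_complex
CD247	CD3_complex
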