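degree	betweenness	closeness	stress
POMC	BDNF	BDNF	BDNF
BDNF	IL6	FOS	IL6
FOS	FOS	POMC	FOS
CRH	FKBP5	CRH	POMC
NPS	ADCYAP1	NPS	NR3C1
HTR1A	POMC	CREB1	FKBP5
NPY	PIN1	TAC1	C1orf56
DRD2	C1orf56	NPY	PIN1
NR3C1	NR3C1	NR3C1	ADCYAP1
CREB1	OGN	CRHR1	CRH
CRHR1	PTGIS	IL6	OGN
TAC1	CCAR1	HTR1A	CCAR1
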