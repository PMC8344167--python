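gene	direction	reference
POMC	up	Meyerhoff JL et al
BDNF	down	Dell'Osso L et al
FOS	up	Segman RH et al
NR3C1	up	Vukojevic V et al
CRH	na	Asalgoo S et al
IL6	up	Gill J et al
NPS	na	Ionescu IA et al
HTR1A	up	Sullivan et al
NPY	down	Cohen H et al
CREB1	down	Segman RH et al
CRHR1	up	Mehta D, Binder EB
TAC1	down	Lindberg J
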