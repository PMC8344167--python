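gene	description	degree	betweenness	closeness	stress	disease_score
POMC	Proopiomelanocortin	32	0.10	0.56	1908	2.1
BDNF	Brain-derived neurotrophic factor	31	0.13	0.58	2120	2.6
FOS	FBJ murine osteosarcoma viral oncogene homolog	31	0.11	0.56	2060	2.0
NR3C1	Nuclear receptor subfamily 3, group C, member 1 (glucocorticoid receptor)	21	0.08	0.51	1806	2.5
CRH	Corticotropin releasing hormone	27	0.04	0.53	1124	2.7
IL6	Interleukin 6 (interferon, beta 2)	20	0.12	0.50	2068	1.5
NPS	Neuropeptide S	27	0.03	0.53	880	1.6
HTR1A	5-hydroxytryptamine (serotonin) receptor 1A, G protein-coupled	25	0.02	0.50	746	2.0
NPY	Neuropeptide Y	24	0.02	0.52	682	2.3
CREB1	Camp responsive element binding protein 1	21	0.05	0.52	976	1.4
CRHR1	Corticotropin releasing hormone receptor 1	21	0.04	0.51	934	2.5
TAC1	Tachykinin, precursor 1	21	0.03	0.52	890	1.2
FKBP5	FK506 binding protein 5	6	0.10	0.42	1748	3.0
ADCYAP1	Adenylate cyclase activating polypeptide 1 (pituitary)	15	0.10	0.48	1376	1.8
PIN1	Peptidylprolyl cis/trans isomerase, NIMA-interacting 1	3	0.09	0.32	1606	1.7
C1orf56	Chromosome 1 open reading frame 56	7	0.09	0.41	1638	1.8
OGN	Osteoglycin	3	0.07	0.25	1112	3.8
CCAR1	Cell division cycle and apoptosis regulator 1	2	0.06	0.31	1074	1.8
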