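snp	gene	genotype	code	control	UADT_inside	UADT_outside
MPO_G-463A	MPO	GG	0	141	70	7
MPO_G-463A	MPO	GA	1	45	34	6
MPO_G-463A	MPO	AA	2	10	9	4
SULT1A1_Arg213His	SULT1A1	Arg/Arg	0	132	60	4
SULT1A1_Arg213His	SULT1A1	Arg/His	1	60	43	13
SULT1A1_Arg213His	SULT1A1	His/His	2	2	6	0
mEH_Tyr113His	mEH	Tyr/Tyr	0	78	25	6
mEH_Tyr113His	mEH	Tyr/His	1	95	53	6
mEH_Tyr113His	mEH	His/His	2	22	18	3
hOGG1_Ser326Cys	hOGG1	Ser/Ser	0	114	49	7
hOGG1_Ser326Cys	hOGG1	Ser/Cys	1	62	51	7
hOGG1_Ser326Cys	hOGG1	Cys/Cys	2	14	8	3
XRCC1_Arg280His	XRCC1	Arg/Arg	0	157	80	14
XRCC1_Arg280His	XRCC1	Arg/His	1	33	30	2
XRCC1_Arg280His	XRCC1	His/His	2	4	4	1
BRCA2_Asn372His	BRCA2	Asn/Asn	0	81	30	5
BRCA2_Asn372His	BRCA2	Asn/His	1	70	50	6
BRCA2_Asn372His	BRCA2	His/His	2	35	14	4
CCND1_A870G	CCND1	GG	0	67	33	11
CCND1_A870G	CCND1	GA	1	93	55	4
CCND1_A870G	CCND1	AA	2	45	27	2
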