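type	lineage	family	male_pct	female_pct
retroelement	Ty3/gypsy	Ogre	11.94	13.24
retroelement	Ty3/gypsy	Tat	2.38	2.51
retroelement	Ty3/gypsy	Athila	11.95	12.22
retroelement	Ty3/gypsy	Tekay	6.90	6.99
retroelement	Ty3/gypsy	CRM	0.26	0.26
retroelement	Ty3/gypsy	other	0.34	0.35
retroelement	Ty1/copia	Angela	11.75	11.83
retroelement	Ty1/copia	Maximus	1.65	1.64
retroelement	Ty1/copia	other	0.28	0.27
retroelement	TRIM	TRIM	0.04	0.04
retroelement	LINE	LINE	0.23	0.23
dna_transposon	CACTA	CACTA	1.25	1.25
dna_transposon	Mutator	Mutator	0.20	0.19
satellite	-	STAR-C	1.92	1.93
satellite	-	X43.1	0.99	1.11
satellite	-	15Ssp	0.09	0.08
satellite	-	TRAYC-like	0.09	0.08
rdna	-	45S_rDNA	0.31	0.44
rdna	-	5S_rDNA	0.03	0.04
unclassified	-	unclassified	6.89	6.72
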