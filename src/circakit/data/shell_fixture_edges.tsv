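src	dst	type	source	pubmed_ids	confidence
BMAL1	PER1	activation	textmine	11111111	0.9
BMAL1	PER2	activation	textmine	11111112	0.9
BMAL1	PER3	activation	textmine	11111113	0.9
BMAL1	CRY1	activation	textmine	11111114	0.9
BMAL1	CRY2	activation	textmine	11111115	0.9
BMAL1	REV-ERBA	activation	both	11111116	0.9
BMAL1	REV-ERBB	activation	string		0.8
CLOCK	PER1	activation	textmine	11111117	0.9
CLOCK	PER2	activation	textmine	11111118	0.9
CLOCK	CRY1	activation	string		0.8
NPAS2	PER1	activation	textmine	11111119	0.8
PER1	CRY1	other	textmine	11111120	0.8
PER2	CRY2	other	textmine	11111121	0.8
PER2	CRY1	other	string		0.8
REV-ERBA	BMAL1	inhibition	textmine	11111122	0.9
REV-ERBB	BMAL1	inhibition	textmine	11111123	0.9
RORA	BMAL1	activation	textmine	11111124	0.9
RORB	BMAL1	activation	string		0.8
RORG	BMAL1	activation	string		0.8
BMAL2	PER2	activation	string		0.7
AHR	PER1	inhibition	textmine	21111101	0.8
ALAS1	BMAL1	other	textmine	21111102	0.7
AMPK	CRY1	inhibition	textmine	21111103	0.9
BTRC	PER2	inhibition	textmine	21111104	0.9
CAR	BMAL1	other	string		0.7
CBP	CLOCK	activation	textmine	21111105	0.9
CK2	BMAL1	other	textmine	21111106	0.8
CREB	PER1	activation	textmine	21111107	0.9
CSNK1D	PER2	inhibition	textmine	21111108	0.9
CSNK1E	PER1	inhibition	textmine	21111109	0.9
CSNK2A1	PER2	other	textmine	21111110	0.8
DBP	PER1	activation	textmine	21111111	0.8
DEC1	BMAL1	inhibition	textmine	21111112	0.8
DEC2	BMAL1	inhibition	textmine	21111113	0.8
E4BP4	PER2	inhibition	textmine	21111114	0.8
FBXL3	CRY1	inhibition	textmine	21111115	0.9
GSK3B	CLOCK	inhibition	textmine	31111101	0.9
GSK3B	PER2	inhibition	string		0.8
HLF	PER1	activation	textmine	31111102	0.7
IFNA	CLOCK	inhibition	textmine	31111103	0.7
NONO	PER1	other	textmine	31111104	0.9
P300	BMAL1	activation	textmine	31111105	0.9
PARP1	CLOCK	other	textmine	31111106	0.8
PPARA	BMAL1	activation	textmine	31111107	0.9
PPARG	REV-ERBA	other	textmine	31111108	0.8
PRKCA	CLOCK	other	textmine	31111109	0.7
RACK1	BMAL1	inhibition	textmine	31111110	0.8
SIRT1	BMAL1	other	textmine	31111111	0.9
TEF	PER1	activation	string		0.7
TNFA	PER1	inhibition	textmine	31111112	0.8
TNFA	CLOCK	inhibition	string		0.7
WDR5	PER1	other	textmine	31111113	0.7
WEE1	CLOCK	other	textmine	31111114	0.8
MYC	PER1	inhibition	textmine	31111115	0.8
CCND1	BMAL1	other	textmine	31111116	0.7
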