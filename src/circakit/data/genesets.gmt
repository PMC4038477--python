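core_clock	canonical core-clock feedback-loop genes	PER1	PER2	PER3	CRY1	CRY2	BMAL1	BMAL2	REV-ERBA	REV-ERBB	RORA	RORB	RORG	CLOCK	NPAS2
clock_related	clock-related genes beyond the core loops	AHR	ALAS1	AMPK	BTRC	CAR	CBP	CK2	CREB	CSNK1D	CSNK1E	CSNK2A1	DBP	DEC1	DEC2	E4BP4	FBXL3	GSK3B	HLF	IFNA	NONO	P300	PARP1	PPARA	PPARG	PRKCA	RACK1	SIRT1	TEF	TNFA	WDR5
cancer_related	selected colon-cancer-related genes	AKT	APC	ATF2	AXIN	BAD	BAX	CTNNB1	BRAF	CD21	CD24	CDC4	FOS	JUN	DPYD	DSH	DUSP16	ELK1	EPHB2	ERCC1	ERCC2	ERK	FGFR1	FOXM1	FZD7	GRB2	GSK3A	GSK3B	GSTP1	HGF	HRAS	IGF2R	JNKK	KRAS	MAPK1	MAP2K2	MCC1	MDM2	MEK	MEKK1	MET	MTHFR	NRAS	PAK	PDK1	PRKCA	CDKN2A	P70S6K	PI3K	PLA2	PLA2G10	PLC	PLD	RAF	RAL	RALGDS	RBP	RHO	RON	RSK	SFRP4	SHC	SMAD4	SOS	TCF4	TGFBR2	TNFA	TNFR1	TP53	TYMS	UGT1A1	VEGF	WNT	XRCC1	XRCC3
discriminative	strong/weak oscillator discriminative signature	APOBEC3F	AQR	ARGLU1	ATP8B3	CAPN6	CBX7	CHD4	CHRNB4	CTCF	CTSB	DTNB	FBXO17	FOXA1	GNG11	GPRASP2	HNF4G	HYAL2	IFNGR2	INO80C	KHDRBS3	LOXL2	MAP1B	NINJ1	NUDT4P1	PDHX	PITX2	PPARD	PPFIBP1	RAB6B	RBPMS	RFWD2	SCN5A	SEC14L2	SLC37A3	SLC39A5	SNORD58A	SNRPA	SPARC	ST3GAL5	STARD8	TBCD	TSPAN9	USP22	WASF3	XYLT2
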