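alias	symbol
ARNTL	BMAL1
ARNTL2	BMAL2
MOP3	BMAL1
NR1D1	REV-ERBA
NR1D2	REV-ERBB
RORC	RORG
EP300	P300
CREBBP	CBP
NFIL3	E4BP4
BHLHE40	DEC1
BHLHE41	DEC2
SHARP2	DEC1
SHARP1	DEC2
TNF	TNFA
PRKAA1	AMPK
BTRCP	BTRC
CSNK2A	CSNK2A1
COP1	RFWD2
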