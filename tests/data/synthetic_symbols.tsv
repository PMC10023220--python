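approved_symbol	alias_symbols	previous_symbols
DHX15	DDX15	HRH2
GEMIN7	SIP3
CDC40	PRP17|EHB3
SNRNP70	U1-70K	SNRP70
SNRPA1
SNRPC
SRRM1	SRM160
TP53	P53|LFS1
MDM2	HDM2
BRCA1
EGFR	ERBB1
KRAS		KRAS2
CDKN2A	P16|INK4A	CDKN2
MYC	C-MYC
AKT1	PKB
PIK3CA
PTEN		MMAC1
RB1
VEGFA		VEGF
TNF		TNFA
IL6	IFNB2
CXCL8		IL8
GAPDH
ACTB
STAT3
JAK2
MAPK1	ERK2	PRKM1
MAPK3	ERK1	PRKM3
CTNNB1
WNT7B
APC
SMAD4		MADH4|DPC4
NOTCH1	TAN1
DLL4
HIF1A	MOP1
EPO
ERBB2	HER2|NEU	NGL
ESR1		ESR
AR
BCL2
BAX
CASP3	CPP32
CASP9	ICE-LAP6
CDK4
CDK6
CCND1		PRAD1|BCL1
FOXO3		FOXO3A
NFKB1
RELA
TGFB1		TGFB
BMP4		BMP2B
SHH
GLI1
PTCH1		PTCH
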