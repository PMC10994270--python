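PROTEASOME_CORE	20S proteasome core complex subunits	PSMA1	PSMA2	PSMA3	PSMA4	PSMA5	PSMA6	PSMA7	PSMB1	PSMB2	PSMB3	PSMB4	PSMB5	PSMB6	PSMB7	PSMB8
UBIQUITIN_PROTEOLYSIS	Ubiquitin-dependent protein catabolic process	PSMA1	PSMB5	PSMB6	PSMD1	PSMD2	UBB	UBC	UBA52	NEDD8	CUL1	SKP1	FBXW7
DNA_TOPOLOGICAL_CHANGE	DNA topological change and topoisomerase activity	TOP1	TOP2A	TOP2B	TOP1MT	TDP1	TDP2	PARP1	LIG1
DNA_SYNTHESIS	Deoxyribonucleotide biosynthesis and DNA replication	TK1	TK2	DCK	DCTD	TYMS	RRM1	RRM2	POLA1	POLE	PCNA	PRIM1
DNA_DAMAGE_RESPONSE	DNA damage checkpoint and repair	ATM	ATR	CHEK1	CHEK2	BRCA1	BRCA2	RAD51	XRCC1	PARP1	H2AX	MDC1
ALDEHYDE_METABOLISM	Aldehyde dehydrogenase activity and metabolism	ALDH2	ALDH1A1	ALDH3A1	ALDH5A1	ALDH7A1	ADH1B	ADH5	AKR1A1
APOPTOSIS_EXECUTION	Cysteine-type endopeptidase activity in apoptosis	CASP3	CASP6	CASP7	CASP8	CASP9	BAX	BAK1	BID	APAF1	CYCS
VESICLE_TRANSPORT_PM	Vesicle-mediated transport to the plasma membrane	SORL1	VAMP2	STX4	SNAP23	RAB11A	RAB8A	EXOC3	EXOC4	MYO5B	SEC22B
GOLGI_VESICLE_TRANSPORT	Golgi vesicle transport	SORL1	AP1B1	AP1M1	COPA	COPB1	COPB2	ARF1	GGA1	GGA2	CLTC	M6PR
ENDOSOME_TRAFFICKING	Early endosome and retromer trafficking	SORL1	VPS26A	VPS29	VPS35	RAB5A	RAB7A	EEA1	SNX1	SNX3	SNX27
AMYLOID_PROCESSING	Regulation of amyloid-beta formation	APP	BACE1	PSEN1	PSEN2	NCSTN	APH1A	ADAM10	ADAM17	SORL1	APOE
ALZHEIMER_LIKE_TOY	Synthetic Alzheimer-like toy pathway	APP	BACE1	PSEN1	PSEN2	MAPT	APOE	SORL1	TREM2	CLU	PICALM	BIN1	CD33
NEURAL_DIFFERENTIATION	Neural progenitor differentiation	SOX2	NES	PAX6	DCX	NEUROD1	NOTCH1	HES1	DLL1	FOXG1
CELL_CYCLE_S_PHASE	S-phase progression and replication licensing	CCNE1	CDK2	CDC6	CDT1	MCM2	MCM3	MCM7	ORC1	GINS1
OXIDATIVE_STRESS	Response to oxidative stress	SOD1	SOD2	CAT	GPX1	NFE2L2	KEAP1	HMOX1	TXN	PRDX1
CORTICOSTEROID_RESPONSE	Response to corticosteroid	NR3C1	FKBP5	TSC22D3	SGK1	ANXA1	DUSP1	KLF15
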