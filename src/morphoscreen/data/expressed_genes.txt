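PSMA1
PSMA2
PSMA3
PSMA4
PSMA5
PSMA6
PSMA7
PSMB1
PSMB2
PSMB3
PSMB4
PSMB5
PSMB6
PSMB7
PSMB8
PSMD1
PSMD2
UBB
UBC
UBA52
NEDD8
CUL1
SKP1
TOP1
TOP2A
TOP2B
TDP1
TDP2
PARP1
LIG1
TK1
TK2
DCK
DCTD
TYMS
RRM1
RRM2
POLA1
POLE
PCNA
PRIM1
ATM
ATR
CHEK1
CHEK2
BRCA1
RAD51
XRCC1
MDC1
ALDH2
ALDH1A1
ALDH5A1
ALDH7A1
ADH5
AKR1A1
CASP3
CASP6
CASP7
CASP8
CASP9
BAX
BAK1
BID
APAF1
CYCS
SORL1
VAMP2
STX4
SNAP23
RAB11A
RAB8A
EXOC3
EXOC4
MYO5B
SEC22B
AP1B1
AP1M1
COPA
COPB1
COPB2
ARF1
GGA1
GGA2
CLTC
M6PR
VPS26A
VPS29
VPS35
RAB5A
RAB7A
EEA1
SNX1
SNX3
SNX27
APP
BACE1
PSEN1
PSEN2
MAPT
APOE
CLU
PICALM
BIN1
SOX2
NES
PAX6
DCX
NOTCH1
HES1
DLL1
FOXG1
CCNE1
CDK2
CDC6
CDT1
MCM2
MCM3
MCM7
ORC1
GINS1
SOD1
SOD2
CAT
GPX1
NFE2L2
KEAP1
HMOX1
TXN
PRDX1
NR3C1
FKBP5
SGK1
ANXA1
DUSP1
GAPDH
ACTB
TUBB3
VIM
LMNB1
HSPA5
CANX
CALR
ATP5F1A
COX4I1
SLC25A3
MT-CO1
RPL13A
RPS6
EIF4E
HNRNPA1
SRSF1
DDX5
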