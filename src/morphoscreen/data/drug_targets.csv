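parent_drug,target_gene
topotecan,TOP1
irinotecan,TOP1
10-hydroxycamptothecin,TOP1
topotecan,TDP1
ixazomib,PSMB5
ixazomib,PSMB1
ixazomib,PSMB2
bortezomib,PSMB5
bortezomib,PSMB1
bortezomib,PSMB6
bortezomib,PSMA1
carfilzomib,PSMB5
carfilzomib,PSMB2
carfilzomib,PSMB7
doxorubicin,TOP2A
doxorubicin,TOP2B
daunorubicin,TOP2A
epirubicin,TOP2A
mitoxantrone,TOP2A
mitoxantrone,TOP2B
pixantrone,TOP2A
cytarabine,DCK
cytarabine,POLA1
cytarabine,DCTD
gemcitabine,RRM1
gemcitabine,TYMS
gemcitabine,DCK
disulfiram,ALDH2
disulfiram,ALDH5A1
disulfiram,ALDH1A1
compound_001,CASP3
compound_002,SOD1
compound_003,CDK2
compound_004,NR3C1
compound_005,BACE1
compound_006,NOTCH1
compound_007,CHEK1
compound_008,HMOX1
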