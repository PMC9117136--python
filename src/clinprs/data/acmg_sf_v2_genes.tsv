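gene	lof_mechanism
APC	1
ACTA2	0
ACTC1	0
APOB	0
ATP7B	1
BMPR1A	1
BRCA1	1
BRCA2	1
CACNA1S	0
COL3A1	1
DSC2	1
DSG2	1
DSP	1
FBN1	1
GLA	1
KCNH2	1
KCNQ1	1
LDLR	1
LMNA	1
MEN1	1
MLH1	1
MSH2	1
MSH6	1
MUTYH	1
MYBPC3	1
MYH11	0
MYH7	0
MYL2	0
MYL3	0
NF2	1
OTC	1
PCSK9	0
PKP2	1
PMS2	1
PRKAG2	0
PTEN	1
RB1	1
RET	0
RYR1	0
RYR2	0
SCN5A	1
SDHAF2	1
SDHB	1
SDHC	1
SDHD	1
SMAD3	1
SMAD4	1
STK11	1
TGFBR1	0
TGFBR2	0
TMEM43	0
TNNI3	0
TNNT2	0
TP53	1
TPM1	0
TSC1	1
TSC2	1
VHL	1
WT1	1
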