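symbol	canonical	hgnc_id
ABL1	ABL1	HGNC:76
AKT1	AKT1	HGNC:391
ALK	ALK	HGNC:427
APC	APC	HGNC:583
ATM	ATM	HGNC:795
BRAF	BRAF	HGNC:1097
BRCA1	BRCA1	HGNC:1100
BRCA2	BRCA2	HGNC:1101
CDH1	CDH1	HGNC:1748
CDKN2A	CDKN2A	HGNC:1787
CSF1R	CSF1R	HGNC:2433
CTNNB1	CTNNB1	HGNC:2514
DDR2	DDR2	HGNC:2731
EGFR	EGFR	HGNC:3236
ERBB2	ERBB2	HGNC:3430
ERBB4	ERBB4	HGNC:3432
ESR1	ESR1	HGNC:3467
EZH2	EZH2	HGNC:3527
FBXW7	FBXW7	HGNC:16712
FGFR1	FGFR1	HGNC:3688
FGFR2	FGFR2	HGNC:3689
FGFR3	FGFR3	HGNC:3690
FLT3	FLT3	HGNC:3765
GNAQ	GNAQ	HGNC:4390
GNAS	GNAS	HGNC:4392
HRAS	HRAS	HGNC:5173
IDH1	IDH1	HGNC:5382
IDH2	IDH2	HGNC:5383
JAK2	JAK2	HGNC:6192
JAK3	JAK3	HGNC:6193
KEAP1	KEAP1	HGNC:23177
KIT	KIT	HGNC:6342
KRAS	KRAS	HGNC:6407
MAP2K1	MAP2K1	HGNC:6840
MET	MET	HGNC:7029
MLH1	MLH1	HGNC:7127
NF1	NF1	HGNC:7765
NOTCH1	NOTCH1	HGNC:7881
NRAS	NRAS	HGNC:7989
PDGFRA	PDGFRA	HGNC:8803
PIK3CA	PIK3CA	HGNC:8975
PTEN	PTEN	HGNC:9588
PTPN11	PTPN11	HGNC:9644
RB1	RB1	HGNC:9884
RET	RET	HGNC:9967
ROS1	ROS1	HGNC:10261
SMAD4	SMAD4	HGNC:6770
STK11	STK11	HGNC:11389
TP53	TP53	HGNC:11998
ABL	ABL1	HGNC:76
AKT	AKT1	HGNC:391
PKB	AKT1	HGNC:391
CD246	ALK	HGNC:427
BRAF1	BRAF	HGNC:1097
RAFB1	BRAF	HGNC:1097
P16	CDKN2A	HGNC:1787
INK4A	CDKN2A	HGNC:1787
FMS	CSF1R	HGNC:2433
CTNNB	CTNNB1	HGNC:2514
ERBB	EGFR	HGNC:3236
ERBB1	EGFR	HGNC:3236
HER1	EGFR	HGNC:3236
HER2	ERBB2	HGNC:3430
NEU	ERBB2	HGNC:3430
HER4	ERBB4	HGNC:3432
FBW7	FBXW7	HGNC:16712
CD135	FLT3	HGNC:3765
C-KIT	KIT	HGNC:6342
CD117	KIT	HGNC:6342
KRAS2	KRAS	HGNC:6407
MEK1	MAP2K1	HGNC:6840
HGFR	MET	HGNC:7029
HNPCC	MLH1	HGNC:7127
P53	TP53	HGNC:11998
LKB1	STK11	HGNC:11389
MMAC1	PTEN	HGNC:9588
SHP2	PTPN11	HGNC:9644
PTC	RET	HGNC:9967
MCF3	ROS1	HGNC:10261
DPC4	SMAD4	HGNC:6770
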