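ribosome	KEGG hsa03010 cytosolic ribosomal proteins	RPL3	RPL4	RPL5	RPL6	RPL7	RPL8	RPL9	RPL10	RPL11	RPL13	RPS2	RPS3	RPS4X	RPS5	RPS6	RPS7	RPS8	RPS9	RPS10	RPS11
cell cycle	KEGG hsa04110	CCNA2	CCNB1	CCNB2	CCND1	CCNE1	CDK1	CDK2	CDK4	CDK6	CDC20	CDC25A	CDC25C	E2F1	E2F2	RB1	TP53	WEE1	BUB1	PLK1	MCM2
VEGF	KEGG hsa04370 VEGF signaling	VEGFA	VEGFB	VEGFC	FLT1	FLT4	KDR	NRP1	NRP2	PIK3CA	AKT1	MAPK1	MAPK3	PLCG1	PTGS2	PXN	SRC	SHC2	NOS3	HSPB1	RAC1
ERBB2	KEGG hsa04012 ErbB signaling	ERBB2	ERBB3	ERBB4	EGFR	NRG1	NRG2	GRB2	SOS1	SHC1	PIK3CA	AKT1	MAPK1	MAPK3	STAT5A	MYC	CBL	PAK1	JUN	ABL1	CRK
PDGFRB	NCBI PID PDGFRB pathway	PDGFRB	PDGFB	PDGFA	GRB2	SOS1	STAT1	STAT3	PIK3CA	PLCG1	SHC1	RASA1	PTPN11	CRK	NCK1	LRP1	ACTA2	MYC	JAK1	FOS	SRC
MAPK	KEGG hsa04010 MAPK signaling	MAPK1	MAPK3	MAPK8	MAPK9	MAPK14	MAP2K1	MAP2K2	MAP3K1	RAF1	BRAF	HRAS	KRAS	NRAS	DUSP1	FOS	JUN	MYC	ELK1	ATF2	NFKB1
WNT	KEGG hsa04310 Wnt signaling	WNT1	WNT3A	WNT5A	FZD1	FZD7	LRP5	LRP6	CTNNB1	APC	AXIN1	GSK3B	TCF7	LEF1	DVL1	MYC	CCND1	CDH1	DKK1	SFRP1	WIF1
TGF-beta	KEGG hsa04350 TGF-beta signaling	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	SMAD7	BMP2	BMP4	BMPR1A	ACVR1	INHBA	THBS1	DCN	LTBP1	ID1	SKP1	E2F4
JAK-STAT	KEGG hsa04630 JAK-STAT signaling	JAK1	JAK2	JAK3	TYK2	STAT1	STAT2	STAT3	STAT4	STAT5A	STAT5B	STAT6	IL6	IL6R	SOCS1	SOCS3	PIAS1	PTPN6	OSM	LIF	CSF2
p53	KEGG hsa04115 p53 signaling	TP53	MDM2	MDM4	CDKN1A	CDKN2A	BAX	BBC3	PMAIP1	PUMA	GADD45A	SFN	SESN1	RRM2B	TP53I3	SERPINB5	THBS1	IGFBP3	CCNG1	ZMAT3	PERP
PI3K-AKT	KEGG hsa04151 PI3K-Akt signaling	PIK3CA	PIK3CB	PIK3R1	AKT1	AKT2	AKT3	PTEN	PDK1	MTOR	RPS6KB1	GSK3B	FOXO1	FOXO3	BAD	TSC1	TSC2	RHEB	EIF4EBP1	IGF1R	INSR
NOTCH	KEGG hsa04330 Notch signaling	NOTCH1	NOTCH2	NOTCH3	NOTCH4	JAG1	JAG2	DLL1	DLL3	DLL4	RBPJ	HES1	HES5	HEY1	HEY2	ADAM17	PSEN1	PSEN2	NUMB	DTX1	MAML1
apoptosis	KEGG hsa04210 apoptosis	BCL2	BCL2L1	MCL1	BAX	BAK1	BID	CASP3	CASP7	CASP8	CASP9	APAF1	CYCS	FAS	FASLG	TNF	TNFRSF1A	BIRC2	BIRC3	XIAP	DIABLO
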