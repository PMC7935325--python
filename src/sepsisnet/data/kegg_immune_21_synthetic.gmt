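hematopoietic cell lineage (hsa04640)	synthetic representative subset	CD34	CD38	KIT	FLT3	CSF1R	CSF2RA	CSF3R	EPOR	MME	CD19	CD4	CD8A	IL7R	ANPEP	ITGA2B
complement and coagulation cascades (hsa04610)	synthetic representative subset	C3	C5	C6	C7	C1QA	C1QB	CR2	F2	F11	FGG	SERPINE1	SERPIND1	PLG	CFB	C5AR1
platelet activation (hsa04611)	synthetic representative subset	GP5	GP9	ITGA2B	ITGB3	F2	FGG	COL1A1	COL3A1	ADCY6	MYLK4	PLCB2	P2RX1
Toll-like receptor signaling (hsa04620)	synthetic representative subset	TLR1	TLR2	TLR4	TLR5	TLR6	MYD88	IRAK1	IRAK4	TRAF6	TICAM1	CD14	LY96	NFKB1	IL6	TNF
Toll and Imd signaling (hsa04624)	synthetic representative subset	PELI1	TAB2	MAP3K7	IKBKB	CHUK	RELA	MYD88	TRAF6	FADD	CASP8
NOD-like receptor signaling (hsa04621)	synthetic representative subset	NOD1	NOD2	NLRP3	NLRP12	CASP1	PYCARD	RIPK2	NAIP	GBP5	IL1B	IL18	NFKB1
RIG-I-like receptor signaling (hsa04622)	synthetic representative subset	DDX58	IFIH1	MAVS	IRF3	IRF7	TRAF3	TBK1	IKBKE	ISG15	IFNB1
cytosolic DNA-sensing (hsa04623)	synthetic representative subset	CGAS	STING1	ZBP1	AIM2	IFI16	POLR3A	IRF3	TBK1	IL33
C-type lectin receptor signaling (hsa04625)	synthetic representative subset	CLEC7A	CLEC4E	CLEC6A	SYK	CARD9	BCL10	MALT1	PLCG2	RAF1	MAPK1
natural killer cell-mediated cytotoxicity (hsa04650)	synthetic representative subset	NCR1	NCR2	NCR3	KLRK1	KLRD1	PRF1	GZMB	FASLG	KIR2DL1	SH2D1A	FCGR3A	VAV1	LCK
antigen processing and presentation (hsa04612)	synthetic representative subset	HLA-A	HLA-B	HLA-C	HLA-DRA	HLA-DRB1	TAP1	TAP2	TAPBP	B2M	PSME1	CTSS	CD74	IFI30
T cell receptor signaling (hsa04660)	synthetic representative subset	CD247	CD3D	CD3E	CD3G	CD4	CD8A	LCK	ZAP70	LAT	ITK	FYN	PLCG1	GRAP2	CBLB	CTLA4	CD28	PDCD1	RASGRP1
Th1 and Th2 cell differentiation (hsa04658)	synthetic representative subset	GATA3	TBX21	STAT1	STAT4	STAT6	IL4R	IL12RB1	IL12RB2	IFNGR1	JAK1	JAK3	RUNX3	NFATC1	LCK	CD247
Th17 cell differentiation (hsa04659)	synthetic representative subset	RORA	RORC	STAT3	IL6R	IL17A	IL17F	IL21	IL23R	TGFBR1	IRF4	AHR	LCK
IL-17 signaling (hsa04657)	synthetic representative subset	IL17A	IL17F	IL17RA	TRAF3IP2	MAPK14	CXCL1	CXCL8	CCL2	MMP9	LCN2	S100A8	NFKB1
B cell receptor signaling (hsa04662)	synthetic representative subset	CD19	CD79A	CD79B	BLNK	BTK	SYK	LYN	PLCG2	PIK3CD	VAV2	CD22	CD72	RASGRP3
Fc epsilon RI signaling (hsa04664)	synthetic representative subset	FCER1A	FCER1G	MS4A2	LYN	SYK	FYN	BTK	PLCG1	PRKCA	VAV1	PIK3CG	IL3	IL4	IL13
Fc gamma R-mediated phagocytosis (hsa04666)	synthetic representative subset	FCGR1A	FCGR2A	FCGR3A	SYK	HCK	LYN	VAV1	RAC1	ARPC2	WASF2	PLCG2	PRKCE	AMPH	MARCKS
leukocyte transendothelial migration (hsa04670)	synthetic representative subset	ICAM1	VCAM1	PECAM1	ESAM	CLDN5	OCLN	ITGAL	ITGAM	ITGB2	CXCR4	NCF2	VAV1	RAC2	CTNNB1	MYL2
intestinal immune network for IgA production (hsa04672)	synthetic representative subset	TNFSF13	TNFSF13B	TNFRSF13B	TNFRSF17	AICDA	CD40	CD40LG	IL10	IL15	TGFB1	CCR9	CCR10	MADCAM1	PIGR
chemokine signaling (hsa04062)	synthetic representative subset	CCL2	CCL5	CXCL8	CXCL10	CCR1	CCR2	CCR5	CXCR1	CXCR2	CXCR4	GNAI2	JAK2	STAT3	PRKCB	ADCY6	PIK3CG	VAV1	ITK
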