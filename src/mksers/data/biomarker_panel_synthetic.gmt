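RBsig	SYNTHETIC placeholder member list for the Rb loss-of-function (E2F target) signature of Malorni et al.; the published list is not redistributed here	E2F1	E2F2	E2F8	CCNE1	CCNE2	CCNA2	CDC6	CDC25A	CDT1	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	PCNA	RRM2	TYMS	TK1	CDC45	GINS1	GINS2	ORC1	ORC6	POLE2	FEN1	EXO1	RFC4	CHAF1A	DHFR
IRPS	SYNTHETIC placeholder member list (35 genes) for the interferon-related palbociclib-resistance signature of De Angelis et al.	STAT1	STAT2	IRF1	IRF7	IRF9	ISG15	IFI6	IFI27	IFI35	IFI44	IFI44L	IFIT1	IFIT2	IFIT3	IFITM1	IFITM3	MX1	MX2	OAS1	OAS2	OAS3	OASL	RSAD2	BST2	XAF1	USP18	HERC5	HERC6	SAMD9	SAMD9L	PARP9	PARP14	DDX58	DDX60	GBP1
CCNE1	cyclin E1 single-gene marker of CDK4/6-inhibitor resistance	CCNE1
TILs_metagene	SYNTHETIC placeholder member list for the T-cell infiltration metagene of Rody et al.	CD2	CD3D	CD3E	CD3G	CD8A	CD247	GZMA	GZMB	GZMK	PRF1	LCK	ZAP70	ITK	IL2RB	CCL19	CXCL13	TRAT1	SH2D1A
Tcell_inflamed_GEP	SYNTHETIC placeholder member list for the 18-gene T-cell-inflamed gene-expression profile of Ayers et al.; published per-gene weights not redistributed, defaults 1	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
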