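TGF_BETA_SIGNALLING	TGF-beta signalling pathway	TGFBR2	APC	CDH1	CREBBP	EP300	SMAD3	TSC2	SMAD4
TGF_BETA_SMAD_DEPENDENT	Altered TGF-beta SMAD-dependent signalling	TGFBR2	SMAD3	FBXW7
P53_PATHWAY	p53 pathway and p21 cell-cycle inhibitor activation	TP53	CDKN1A	CDKN2A	MYC	EP300
E_CADHERIN_SIGNALLING	E-cadherin signalling events	CDH1	CTNNB1	EGFR
FOXO_SIGNALLING	FOXO family signalling	FOXO1	FOXO3	AKT1	GSK3B	CREBBP
MAPK_SIGNALLING	MAPK signalling cascade	KRAS	MAP2K1	MAPK1	TNF	MYC
SMAD2_3_REGULATION	Regulation of nuclear SMAD2/3 signalling	SMAD2	SMAD3	SMAD4	EP300	CREBBP
ERBB1_SIGNALLING	ERBB1 (EGFR) downstream signalling	EGFR	KRAS	GSK3B	MYC	ROCK1
CMET_SIGNALLING	c-MET receptor signalling	MET	KRAS	ROCK1	CRK
NOTCH_HES_HEY	Notch-mediated HES/HEY network	NOTCH1	HES1	HEY1	CREBBP
L1CAM_INTERACTIONS	L1CAM neural adhesion interactions	ANK2	CLTC	LAMC1	DCX	KCNQ3	NRP2	SCN2A	SPTBN1	ITGA9	SPTBN2
AXON_GUIDANCE	Axon guidance signalling	ANK2	ARHGEF12	CLTC	GSK3B	LAMC1	MYH9	PLXNA2	RGMA	RGMB	RND1	SEMA6A	SRGAP2	KRAS	MET	ROCK1	COL1A2	COL3A1	ITGA9	SPTBN2
WNT_SIGNALLING	Wnt signalling pathway	APC	CTNNB1	GSK3B	MYC
HEDGEHOG_SIGNALLING	Hedgehog signalling pathway	GLI1	PTCH1	SMO
DNA_DAMAGE_REPAIR	DNA damage repair	TP53	EP300	ERCC4	FBXW7
PAIN_PERCEPTION	Pain perception biological process	NTRK1	TNF	SCN2A
DICER_PROCESSING	DICER1 miRNA processing perturbation	DICER1	TP53	CDH1
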