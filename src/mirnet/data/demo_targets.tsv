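# synthetic demo miRNA -> validated-target map (illustrative only)
hsa-miR-103	FBXW7
hsa-miR-103	VCP
hsa-miR-103	CHD1
hsa-miR-103	PCDH17
hsa-miR-103	HIP1
hsa-miR-103	TGFBR2
hsa-miR-103	TNF
hsa-miR-563	ITGA9
hsa-miR-563	SPTBN2
hsa-miR-563	COL1A2
hsa-miR-563	COL3A1
hsa-miR-199b-5p	ANK2
hsa-miR-199b-5p	CLTC
hsa-miR-199b-5p	LAMC1
hsa-miR-199b-5p	ARHGEF12
hsa-miR-199b-5p	GSK3B
hsa-miR-199b-5p	MYH9
hsa-miR-199b-5p	PLXNA2
hsa-miR-199b-5p	RGMA
hsa-miR-199b-5p	RGMB
hsa-miR-199b-5p	RND1
hsa-miR-199b-5p	SEMA6A
hsa-miR-199b-5p	SRGAP2
hsa-miR-323-3p	ANK2
hsa-miR-323-3p	DCX
hsa-miR-323-3p	KCNQ3
hsa-miR-323-3p	LAMC1
hsa-miR-323-3p	NRP2
hsa-miR-323-3p	SCN2A
hsa-miR-323-3p	SPTBN1
hsa-miR-323-3p	NTRK1
hsa-miR-323-3p	TNF
hsa-let-7g	TP53
hsa-let-7g	CDKN2A
hsa-let-7g	FBXW7
hsa-let-7g	FN1
hsa-let-7g	MYC
hsa-let-7g	TBX5
hsa-let-7g	GLI1
hsa-let-7g	TNF
hsa-let-7g	ERCC4
hsa-miR-221	TP53
hsa-miR-221	CDKN2A
hsa-miR-221	MYC
hsa-miR-221	TNF
hsa-miR-140-5p	TP53
hsa-miR-140-5p	CDH1
hsa-miR-548b-3p	DICER1
hsa-miR-21	TGFBR2
hsa-miR-21	SMAD3
hsa-miR-21	SMAD4
hsa-miR-214	TGFBR2
hsa-miR-146a	SMAD3
hsa-miR-146a	SMAD4
hsa-miR-181a	SMAD4
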