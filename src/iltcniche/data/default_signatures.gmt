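gdT	gamma-delta T lineage markers	TRDC	TRGC1	TRGC2	KLRD1	B2M
MAIT	MAIT markers	KLRB1	DPP4	CXCR6	IL7R
iNKT	iNKT markers (editable placeholder; canonical field markers)	ZBTB16	CD1D	KLRB1	IL2RB
panT	pan-T markers	CD3D	CD3E	CD3G	CD2	TRAC
fibroblast	fibroblast markers	COL1A1	COL1A2	COL3A1	PDGFRB	LUM	DCN
keratinocyte	keratinocyte markers	KRT5	KRT14	KRT1	KRT10	KRTDAP	DSP
residency	tissue-residency programme	ITGAE	ITGA1	CD69	CXCR6	ZNF683
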