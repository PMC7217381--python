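# Synthetic stand-in for a curated 14-gene fibrosis signature (tissue
# fibrosis mediators expressed by megakaryocyte progenitors).  Edit or
# replace with a curated list for real analyses.
fibrosis	TGFB1
fibrosis	LTBP1
fibrosis	TNF
fibrosis	PDGFA
fibrosis	CCL5
fibrosis	CXCL5
fibrosis	COL1A1
fibrosis	COL3A1
fibrosis	FN1
fibrosis	SPARC
fibrosis	TIMP1
fibrosis	SERPINE1
fibrosis	CTGF
fibrosis	THBS1
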