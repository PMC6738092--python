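cohort	lvi_positive	total
Nottingham	117	285
other-METABRIC	518	1280
METABRIC-all	635	1565
TCGA	295	854
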