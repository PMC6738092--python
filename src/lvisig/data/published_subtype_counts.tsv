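cohort	factor	level	subtype1	subtype2
METABRIC	lvi_status	positive	262	373
METABRIC	lvi_status	negative	476	454
METABRIC	tumour_size	ge2cm	454	613
METABRIC	tumour_size	lt2cm	279	202
METABRIC	nodal_status	positive	307	428
METABRIC	nodal_status	negative	429	396
METABRIC	grade	grade3	187	586
METABRIC	grade	grade1-2	519	219
METABRIC	er	positive	707	497
METABRIC	er	negative	31	330
METABRIC	pr	positive	533	295
METABRIC	pr	negative	205	532
METABRIC	her2	positive	20	168
METABRIC	her2	negative	718	659
METABRIC	molecular_subtype	LuminalA	467	126
METABRIC	molecular_subtype	LuminalB	121	272
METABRIC	molecular_subtype	HER2-enriched	10	171
METABRIC	molecular_subtype	Basal-like	24	222
METABRIC	molecular_subtype	Normal-like	113	35
TCGA	lvi_status	positive	61	234
TCGA	lvi_status	negative	202	357
TCGA	tumour_size	ge2cm	164	451
TCGA	tumour_size	lt2cm	99	140
TCGA	nodal_status	positive	128	295
TCGA	nodal_status	negative	134	292
TCGA	grade	grade3	28	324
TCGA	grade	grade1-2	219	245
TCGA	er	positive	246	393
TCGA	er	negative	6	179
TCGA	pr	positive	235	311
TCGA	pr	negative	15	257
TCGA	her2	positive	20	113
TCGA	her2	negative	189	378
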