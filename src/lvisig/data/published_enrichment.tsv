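ontology_id	name	genes_in_ontology	expected	p_printed	members
GO:0005615	Extracellular space	1385	6.52	<0.0001	SERPINA3;DCN;CFD;FBLN1;DKK3;ANG;GSTP1;ANXA1;HBB;HSPB1;APOC1;APOE;MFAP4;NDP;SERPINE2;S100A4;CFB;CXCL12;C1S;ACTG2;YWHAZ;STC2;CXCL14
GO:0072562	Blood microparticle	110	0.52	0.00043	SERPINA3;HBB;APOE;CFB;C1S;ACTG2;YWHAZ
GO:0031012	Extracellular matrix	503	2.37	0.0079	DCN;FBLN1;ANG;HSPB1;APOE;MFAP4;MGP;MMP11;NDP;SERPINE2;VIM
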