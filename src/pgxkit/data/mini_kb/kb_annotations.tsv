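rsid	gene	chrom	pos	genotype	drug	aspect	direction	evidence	fda_labeled	description
rs1042522	GENE_CIS1	17	7579472	CC	cisplatin	toxicity	decrease	2A	false	Homozygous CC is associated with decreased toxicity of cisplatin.
rs316019	GENE_CIS2	6	160670282	CC	cisplatin	toxicity	increase	2A	false	Homozygous CC is associated with increased toxicity of cisplatin.
rs11615	GENE_CIS3	19	45923653	AG	cisplatin	toxicity	increase	2B	false	Heterozygous AG is associated with increased toxicity of cisplatin.
rs11615	GENE_CIS3	19	45923653	GG	cisplatin	toxicity	decrease	2B	false	Homozygous GG is associated with decreased toxicity of cisplatin.
rs3957357	GENE_CIS4	6	52668941	TT	cisplatin	toxicity	decrease	3	false	Synthetic fixture genotype: TT assigned decreased cisplatin toxicity for testing.
rs9923231	VKORC1	16	31107689	AA	warfarin	dosage	decrease	1A	true	Homozygous AA promoter variant carriers require a lower warfarin dose.
rs1057910	CYP2C9	10	96741053	CC	warfarin	dosage	decrease	1A	true	CYP2C9*3 homozygotes metabolize warfarin slowly; lower dose recommended.
rs2108622	CYP4F2	19	15990431	TT	warfarin	dosage	increase	1B	true	CYP4F2 V433M homozygotes may require an increased warfarin dose.
rs2108622	CYP4F2	19	15990431	TT	phenprocoumon	dosage	increase	2A	false	CYP4F2 V433M homozygotes may require an increased phenprocoumon dose.
rs2292566	VKORC1	16	31104878	AA	warfarin	dosage	decrease	3	true	Synthetic fixture genotype and gene placement: AA carriers recommended for a lower warfarin dosage.
rs4244285	CYP2C19	10	94781859	AA	clopidogrel	efficacy	decrease	1A	true	CYP2C19*2 poor metabolizers show diminished clopidogrel effectiveness.
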