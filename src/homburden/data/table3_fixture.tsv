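genomic	affected_unaffected	gene	mutation_class	cdna	aa_change	dataset_maf	n_individuals	popmax_af	cadd
chr2:25044490 T>G	1/0	ADCY3	missense	NM_004036:c.3555A>C	E1008A	7.46E-04	10055	2.55E-04	20.5
chr5:170236670 G>A	1/0	GABRP	missense	NM_014211:c.1128G>A	G311R	2.98E-04	10058	9.01E-05	32
chr8:131880120 C>G	1/0	ADCY8	missense	NM_001115:c.2182G>C	A728P	9.94E-05	10056	1.00E-03	18.29
chr11:122929541 T>C	1/0	HSPA8	splice_junction	NM_153201:c.1601-3A>G	.	9.94E-04	10055	3.33E-04	0.66
chr16:76532538 G>A	1/0	CNTNAP4	missense	NM_033401:c.2311G>A	R770Q	2.50E-04	9986	7.52E-05	21.7
chr17:39881003 C>T	1/0	HAP1	missense	NM_177977:c.1810G>A	G604R	1.49E-04	10059	5.22E-02	0.03
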