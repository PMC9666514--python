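# Reference affinity-scale comparison statistics (Spearman rho, RMSD in
# kJ/mol) as reported in the published study this analysis builds on.
# "comparison" names the two scales compared; a solvent suffix in
# parentheses marks cross-solvent comparisons of one base.
# Columns: scale_a, scale_b, solvent, spearman_rho, rmsd_kJ_per_mol
scale_a	scale_b	solvent	spearman_rho	rmsd_kJ_per_mol
5mC	5hmC	water	0.91	0.96
5mC	CYT	water	0.95	0.95
5hmC	CYT	water	0.97	0.96
5mC	5hmC	methanol	0.18	2.04
5mC	CYT	methanol	0.31	1.52
5hmC	CYT	methanol	0.78	0.97
m6A	ADE	water	0.89	0.85
m6A(methanol)	m6A(water)	cross	0.85	2.83
m6A	ADE	methanol	0.87	0.67
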