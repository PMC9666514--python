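# Reference replicate standard deviations of binding free energies (kJ/mol,
# 5 independent repeats per pair) as reported in the published study this
# analysis builds on. Reporting threshold: 0.58 kJ/mol.
# Columns: nucleobase, solvent, residue, sd_kJ_per_mol
nucleobase	solvent	residue	sd_kJ_per_mol
5mC	methanol	Asp	0.55
5mC	methanol	Glu	0.80
5hmC	methanol	Asp	0.73
5hmC	methanol	Glu	0.92
m6A	water	Glu	0.96
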