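# Reference binding free-energy differences DDG (kJ/mol), transcribed from
# the published reference values this analysis builds on (values quoted in
# the running text; sign convention: first base minus second base).
# Columns: comparison, solvent, residue, ddg_kJ_per_mol
comparison	solvent	residue	ddg_kJ_per_mol
5mC-CYT	methanol	Ala	-1.6
5mC-CYT	methanol	Arg	-1.5
5mC-CYT	methanol	Glu	3.1
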