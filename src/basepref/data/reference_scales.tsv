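# Reference absolute binding free energies (kJ/mol) between single modified
# nucleobases and amino-acid side-chain analogs, transcribed from the
# published reference values this analysis builds on.
# PARTIAL transcription: only the values quoted in the running text of the
# source report are available here; the full per-residue tables are not.
# Columns: nucleobase, solvent, residue, dG_kJ_per_mol
nucleobase	solvent	residue	dG_kJ_per_mol
5mC	water	Trp	-4.3
5mC	water	Tyr	-3.9
5mC	water	Phe	-3.0
5hmC	water	Trp	-4.8
5hmC	water	Tyr	-4.2
5hmC	water	Phe	-3.5
m6A	water	Trp	-5.2
m6A	water	Tyr	-5.1
m6A	water	Phe	-3.4
m6A	methanol	Trp	-0.5
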