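# Consensus amino-acid hydrophobicity: Factor I of the multivariate
# consensus analysis of physicochemical property scales (Atchley et al.,
# PNAS 2005, factor I "polarity/accessibility/hydrophobicity").
# Sign convention: hydrophobic residues negative.
# Columns: residue (3-letter), factor1
residue	factor1
Ala	-0.591
Cys	-1.343
Asp	1.050
Glu	1.357
Phe	-1.006
Gly	-0.384
His	0.336
Ile	-1.239
Lys	1.831
Leu	-1.019
Met	-0.663
Asn	0.945
Pro	0.189
Gln	0.931
Arg	1.538
Ser	-0.228
Thr	-0.032
Val	-1.337
Trp	-0.595
Tyr	0.260
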