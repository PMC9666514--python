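#!/usr/bin/env python
"""Compare affinity scales: ddG, Spearman rho, RMSD, outliers.

Uses the packaged reference values (the transcription is partial - only the
entries quoted in the source report's text are available, so the comparison
runs on the aromatic block the transcription covers) and reports the pair
statistics next to the published full-table values for context.
"""

import json
from pathlib import Path

from basepref import scales

OUT = Path(__file__).resolve().parent.parent / "results"

ref = scales.load_reference_scales()
published = scales.load_reference_statistics()

blocks = {}
for (a_key, b_key) in [(("5mC", "water"), ("5hmC", "water")),
                       (("m6A", "water"), ("5mC", "water"))]:
    a, b = ref[a_key], ref[b_key]
    comp = scales.compare_report(a, b, outlier_cutoff=1.0)
    label = f"{a.nucleobase}({a.solvent}) vs {b.nucleobase}({b.solvent})"
    blocks[label] = {
        "residues": comp.residues, "spearman_rho": comp.spearman_rho,
        "rmsd_kJ_per_mol": comp.rmsd, "ddg": comp.ddg, "outliers": comp.outliers,
    }
    print(f"{label}: rho = {comp.spearman_rho:.2f}, "
          f"RMSD = {comp.rmsd:.2f} kJ/mol on {len(comp.residues)} residues; "
          f"|ddG| > 1 outliers: {', '.join(comp.outliers) or 'none'}")

ddg = scales.load_reference_ddg()
print("\nquoted ddG(5mC-CYT, methanol) reference values:")
for row in ddg.itertuples():
    pref = "5mC" if row.ddg_kJ_per_mol < 0 else "CYT"
    print(f"  {row.residue}: {row.ddg_kJ_per_mol:+.1f} kJ/mol (prefers {pref})")

full = published[(published["scale_a"] == "5mC") & (published["scale_b"] == "5hmC")]
print("\npublished full-table statistics for context:")
print(full.to_string(index=False))

(OUT / "scales_comparison.json").write_text(
    json.dumps(blocks, indent=2) + "\n")
print(f"-> {OUT/'scales_comparison.json'}")
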