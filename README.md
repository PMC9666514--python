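# basepref

Interaction preferences between modified DNA/RNA nucleobases and protein
side chains, quantified from first principles.

Covalent nucleobase marks — 5-methylcytosine (5mC), 5-hydroxymethylcytosine
(5hmC) and N6-methyladenine (m6A) — steer epigenetic regulation partly by
changing how strongly protein side chains bind the modified base. This
package implements the computational chain that turns biased distance
sampling along a nucleobase/side-chain separation coordinate into absolute
binding free energies and interaction-mode statistics, for researchers in
structural bioinformatics and molecular biophysics who want the estimators
without a compute cluster: the molecular-dynamics stage is replaced by a
synthetic-data module that draws equilibrium samples from closed-form
potentials of mean force (PMFs), so every estimate can be checked against
exact ground truth.

## What it computes

**PMF and binding free energy.** Umbrella windows at restraining distances
r_i (default 0.4–1.9 nm, step 0.1 nm, force constant k = 500 kJ mol⁻¹ nm⁻²)
are combined by the weighted histogram analysis method (WHAM),

    p(r_j) ∝ Σ_i n_ij / Σ_i N_i exp[β(f_i − U_i(r_j))],
    f_i    = −k_B T ln Σ_j p(r_j) exp[−β U_i(r_j)] Δr,

iterated to self-consistency (f₁ = 0 gauge). The radial Jacobian is removed
and the plateau zeroed, W(r) = −k_B T ln[p(r)/r²] + C, and the
standard-state absolute binding free energy is

    ΔG = −k_B T ln[ (∫₀^{r_c} e^{−W(r)/k_B T} 4πr² dr) / V° ],

with V° = 1.661 nm³ (1 M) and T = 298 K. Convergence follows a split-half
rule: if the ΔG of the two sample halves differs by more than 1.5 kJ/mol,
every window is extended together and the check repeated.

**Interaction modes.** Geometric detectors for π–π stacking, cation–π,
anion–π and hydrogen bonds, with occupancy fractions evaluated at the
umbrella window nearest the PMF minimum. π-based modes are reported as
dominant at occupancy ≥ 50% (inclusive); H-bonds above 10% (strict).

**Affinity-scale statistics.** Per-residue ΔΔG between scales, Spearman ρ
and RMSD over the shared residue set, and outlier detection at a |ΔΔG|
cutoff.

**Interface enrichment.** For PDB complexes containing 5mC (residue 5CM/5MC)
and/or cytosine (DC/C): per-amino-acid enrichment
E = (interface area fraction)/(surface area fraction) with Shrake–Rupley
SASA on the protein chains, pooled over structures, the preference proxy
−ln(E(5mC)/E(CYT)), and its correlation with the consensus Factor 1
hydrophobicity scale.

## Worked example

```sh
python analysis/01_simulate_windows.py
python analysis/02_pmf_free_energy.py
```

prints, for the reference Gaussian well (depth 8 kJ/mol at 0.5 nm):

```
wrote 16 windows (10000 samples each) -> scratch/windows/series.json
...
WHAM converged in 656 iterations -> results/pmf.tsv
PMF minimum -8.10 kJ/mol at 0.499 nm (true well: -8.00 at 0.500)
dG_binding = -5.384 kJ/mol at r_c = 0.799 nm; quadrature oracle -5.282
  -> |error| 0.102 (inside the 0.5 kJ/mol recovery window)
```

The reconstruction finds the planted well to within 0.1 kJ/mol of its depth
and recovers the absolute binding free energy within 0.1 kJ/mol of the exact
quadrature value — comfortably inside the ~1 kJ/mol reproducibility window
that umbrella-sampling replicate studies report. Steps 03–06 run the
convergence policy, the interaction-mode occupancies, the affinity-scale
comparisons and the toy-complex interface enrichment; each writes its tables
under `results/` and prints a short narrative of what it found. The same
functionality is exposed as a CLI (`basepref simulate|pmf|dg|converge|modes|
scales|enrich|run|report`).

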