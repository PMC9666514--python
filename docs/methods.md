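# Methods

## Model and procedure

The package treats nucleobase/side-chain binding as diffusion along a single
reaction coordinate r, the center-of-geometry distance between the two
solutes, with an unknown potential of mean force W(r). The full chain is:

1. **Biased sampling.** Harmonic umbrella biases U_i(r) = ½k(r − r_i)² at a
   ladder of centers enhance coverage of r. The synthetic generator draws
   i.i.d. samples from p_i(r) ∝ r² exp[−β(W*(r) + U_i(r))] for a chosen
   closed-form W*. The r² factor is the 3-D volume element of a radial
   coordinate; including it in the generator makes the downstream Jacobian
   correction a real, testable step rather than a no-op.
2. **WHAM.** Window histograms on shared bins are combined by
   self-consistent iteration of the standard two equations (density update,
   window free-energy constants f_i), gauge-fixed at f₁ = 0. The residual is
   the largest absolute change of any f_i per sweep (in kJ/mol, on the
   gauge-fixed scale); iteration stops below 1e-7 or errors at 1e5 sweeps.
   Non-overlapping adjacent histograms are rejected up front.
3. **PMF.** W(r) = −k_BT ln[p(r)/r²] + C with C chosen so that W averages to
   zero over the large-separation plateau (default 1.7–1.9 nm). Unsampled
   bins are NaN, never silently zero.
4. **Binding free energy.** ΔG = −k_BT ln[(∫₀^{r_c} e^{−βW} 4πr² dr)/V°].
   The integral is evaluated bin-wise with exact spherical-shell volumes
   4π/3 (r₊³ − r₋³), a partial final shell up to r_c, and a constant-W
   extrapolation of the innermost sampled bin over the unsampled core
   [0, r_start] (the core volume is small and the synthetic PMFs are flat
   there; on the closed-form checks this evaluation hits the exact limits to
   1e-3 kJ/mol). Coverage between the PMF minimum and r_c must be gapless;
   a hole there raises an error, whereas ragged low-count bins below the
   well are absorbed into the core extrapolation.
5. **Bound cutoff r_c.** Unless fixed by the caller, r_c is the first grid
   point past the PMF minimum where W ≥ −0.05 k_BT and the mean of the next
   five sampled bins lies within ±0.2 kJ/mol of zero. The lookahead uses a
   mean, not a per-bin test: per-bin counting noise is ~k_BT/√counts and a
   per-bin criterion rarely triggers at realistic sample sizes, pushing r_c
   onto the far plateau and integrating a long noisy tail (which biases ΔG
   down by Jensen's inequality). r_c is deliberately exposed as a
   sensitivity parameter because the bound-region definition is a
   convention.
6. **Convergence control.** Each window's samples are split in order into
   halves (the stand-in for consecutive time segments of a production run);
   the full chain runs on each half and the series counts as converged when
   |ΔG₁ − ΔG₂| ≤ 1.5 kJ/mol. Both halves use one r_c determined from the
   full series — otherwise cutoff jitter between halves masquerades as ΔG
   drift. An unconverged series is extended by a fixed number of samples in
   every window simultaneously and re-checked on the accumulated set; a
   half-series too sparse to estimate at all counts as unconverged rather
   than erroring, since undersampling is precisely what the loop exists to
   repair. Replicate summaries use the sample SD (ddof = 1, appropriate for
   five repeats) and flag values above 0.58 kJ/mol.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| temperature T | 298 | K | simulation temperature of the emulated protocol |
| k_B | 0.0083145 | kJ/mol/K | — |
| force constant k | 500 | kJ/mol/nm² | emulated umbrella protocol |
| bias centers | 0.4–1.9 step 0.1 | nm | 16-window ladder of the protocol |
| bin width | 0.02 | nm | ≥ 5 bins per bias σ (= √(k_BT/k) ≈ 0.07 nm) |
| plateau | [1.7, 1.9] | nm | PMFs flatten to zero at large separation |
| V° | 1.661 | nm³ | 1 M standard state |
| split-half threshold | 1.5 | kJ/mol | convergence rule of the protocol |
| replicate SD threshold | 0.58 | kJ/mol | reporting threshold |
| stacking | ≤ 0.45 nm, ≤ 30° | | conventional geometric criteria; all |
| ion–π | ≤ 0.50 nm, ≤ 45° | | cutoffs config-exposed |
| H-bond | ≤ 0.35 nm, ≥ 150° | | |
| occupancy thresholds | ≥ 0.5 (π), > 0.1 (H-bond) | | inclusive/strict per the reporting wording |
| vdW radii | Bondi | Å | contacts and SASA share one radius set |
| contact tolerance | 0.5 | Å | van-der-Waals contact slack |
| SASA probe, points | 1.4 Å, 960 | | Shrake–Rupley, deterministic point set |
| outlier cutoff | 1.0 (alt. 3.0) | kJ/mol | scale-comparison outlier reporting |

## Synthetic data: what it emulates and what it does not

The generator replaces cluster-scale molecular dynamics with equilibrium
draws from parametric PMFs (flat, square well, Gaussian well, double well)
via inverse-CDF lookup on a 2¹⁴-point grid — deterministic per seed, immune
to rejection-rate collapse at stiff biases. Per-window seeds derive from a
master seed through SeedSequence entropy mixing, so windows are
statistically independent.

Deliberate simplifications, and their consequences:

* **Samples are i.i.d.** Real MD output is autocorrelated; error bars from
  these tests are optimistic, expectations are not. No autocorrelation or
  block-averaging machinery is included.
* **Snapshots use idealized planar six-membered rings** and explicit
  donor/acceptor/charge annotations. Classifiers are therefore tested for
  their geometry logic, not for chemistry perception, which is out of scope
  (ring/charge/donor flags are inputs).
* **Toy complexes use single-CA protein residues** placed at controlled
  radii (interface in van-der-Waals contact, surface fully exposed, buried
  inside an icosahedral Gly cage impenetrable to the 1.4 Å probe). This
  makes planted area compositions analytic while exercising the real PDB
  parsing, SASA and contact code; the cage Gly atoms contribute ordinary Gly
  surface area by design. Passing these tests demonstrates correctness of
  the estimators, not realism of toy geometry.

Consequently, green tests certify the estimators against exact ground
truth; they say nothing about force fields, solvent models or conformational
sampling, which the emulated stage abstracts away.

## Statistics

Scale comparisons run over the intersection of residue labels, with the
three histidine protonation forms (His_A, His_B, His_H) kept as separate
rows. Spearman ρ uses average ranks for ties; RMSD is the root mean square
of per-residue ΔΔG. The packaged reference tables are a *partial*
transcription — only the values quoted in the running text of the source
report were recoverable — so full-table ρ/RMSD values ship as reference
numbers (for context) rather than as recomputable quantities; everything the
partial tables do determine (quoted ΔΔG entries, replicate-SD flags, the
rank structure and RMSD of the transcribed aromatic block) is recomputed and
tested.

Enrichment pools areas over structures before taking ratios ("total relative
surface area" reading); per-structure averaging with bootstrap error bars
over structures is available as an alternative convention. SASA is computed
on the protein chains only — "surface occupied by the amino acid on the
whole surface" reads as protein surface; a flag switches to complex context.
Amino acids absent from every interface get E = 0; the preference proxy is
defined only where both E values are positive, and undefined entries are
reported missing, never coerced to 0. The proxy's sign matches the ΔΔG
convention (negative = prefers 5mC). Note that the pooled E statistic is
monotone under moving residues of one type into contact (surface
composition fixed); growing the protein by adding new contact residues
changes the denominator as well and need not increase E.

The hydrophobicity comparison uses the consensus multivariate Factor I
scale (hydrophobic negative), plain or averaged within the standard
physicochemical groups (apolar; aromatic; OH-containing; amide-containing;
positively/negatively charged; Gly and Pro as singletons), with a two-sided
t-distribution p-value.

## Numerical choices and degenerate inputs

* Histogram edges span the union of the ±3σ bias envelope and the actual
  sample range, so counts are conserved exactly; a window with no in-range
  samples is an error.
* An additive offset on every bias energy cancels in the f₁ = 0 gauge —
  asserted as a property test, as is invariance to window order and count
  rescaling.
* Boundary conventions are inclusive everywhere a cutoff is compared
  (stacking distance at exactly 0.45 nm counts; a contact at exactly
  r_i + r_j + 0.5 Å counts), except the H-bond occupancy reporting
  threshold, which is strict by its wording.
* PMF minimum ties break toward smaller r. Altloc resolution keeps the
  highest occupancy, ties toward the first label. Hydrogens are ignored in
  all area and contact work.
* Problem sizes: the standard test configuration uses 16 windows × 10⁴
  samples (oracle recovery ≤ 0.5 kJ/mol), 200 snapshots per classifier
  ensemble, and two-structure toy suites; these sizes make the full suite
  and the acceptance script run in seconds while leaving the statistical
  assertions comfortably powered.

## Known limitations

* No MBAR generalization, 2-D coordinates, or enthalpy/entropy split.
* No chemistry perception, no mmCIF input, no secondary-structure logic.
* The ΔG-from-PMF expression and the bound-region definition are decided
  conventions (the emulated protocol's source defers them to prior
  methodology); r_c sensitivity should be checked when comparing absolute
  values across studies.
* Reference scale fixtures are partial transcriptions (see Statistics).
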