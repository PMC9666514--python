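"""Affinity-scale algebra and comparison statistics.

An affinity scale maps residue labels to absolute binding free energies
(kJ/mol) for one nucleobase in one solvent. Scales are compared on the
intersection of their residue labels by per-residue ΔΔG, Spearman rank
correlation ρ (average-rank ties), and RMSD; residues whose |ΔΔG| exceeds a
cutoff are reported as outliers. The three histidine protonation forms
(His_A, His_B, His_H) are distinct labels and enter comparisons as separate
rows when present in both scales.

Packaged reference values (partial transcriptions of the published scales —
only prose-quoted entries were recoverable) load via ``load_reference_*``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

NUCLEOBASES = ("CYT", "5mC", "5hmC", "ADE", "m6A")
SOLVENTS = ("water", "methanol")


@dataclass
class AffinityScale:
    nucleobase: str
    solvent: str
    entries: dict[str, float]

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValueError("a scale needs at least 2 entries")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate residue labels")
        if not all(np.isfinite(list(self.entries.values()))):
            raise ValueError("all dG values must be finite")

    def common_residues(self, other: "AffinityScale") -> list[str]:
        return sorted(set(self.entries) & set(other.entries))

    def values_on(self, residues) -> np.ndarray:
        return np.array([self.entries[r] for r in residues], dtype=float)


@dataclass
class ScaleComparison:
    residues: list[str]
    spearman_rho: float
    rmsd: float
    ddg: dict[str, float]              # a − b per residue
    outliers: list[str]                # |ΔΔG| > cutoff
    outlier_cutoff: float
    missing_in_either: list[str] = field(default_factory=list)


def delta_delta_g(a: AffinityScale, b: AffinityScale) -> dict[str, float]:
    """Entry-wise ΔΔG = ΔG_a − ΔG_b on the common residue set."""
    common = a.common_residues(b)
    if not common:
        raise ValueError("scales share no residues")
    return {r: a.entries[r] - b.entries[r] for r in common}


def spearman_rho(a: AffinityScale, b: AffinityScale) -> float:
    """Spearman rank correlation on the common residues (average-rank ties)."""
    common = a.common_residues(b)
    if len(common) < 3:
        raise ValueError("need at least 3 common residues for a rank correlation")
    xa, xb = a.values_on(common), b.values_on(common)
    if np.ptp(stats.rankdata(xa)) == 0 or np.ptp(stats.rankdata(xb)) == 0:
        raise ValueError("zero rank variance")
    rho, _ = stats.spearmanr(xa, xb)
    return float(rho)


def rmsd_scales(a: AffinityScale, b: AffinityScale) -> float:
    """Root-mean-square ΔΔG over the common residues, kJ/mol."""
    ddg = np.array(list(delta_delta_g(a, b).values()))
    return float(np.sqrt(np.mean(ddg**2)))


def compare_report(
    a: AffinityScale,
    b: AffinityScale,
    outlier_cutoff: float = 1.0,
) -> ScaleComparison:
    """Bundle ρ, RMSD, ΔΔG and |ΔΔG| > cutoff outliers for two scales."""
    ddg = delta_delta_g(a, b)
    common = sorted(ddg)
    missing = sorted(set(a.entries) ^ set(b.entries))
    return ScaleComparison(
        residues=common,
        spearman_rho=spearman_rho(a, b),
        rmsd=rmsd_scales(a, b),
        ddg=ddg,
        outliers=sorted([r for r, v in ddg.items() if abs(v) > outlier_cutoff]),
        outlier_cutoff=outlier_cutoff,
        missing_in_either=missing,
    )


# ---------------------------------------------------------------------------
# TSV round-trip and packaged reference data.

def write_scale_tsv(scale: AffinityScale, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"#nucleobase={scale.nucleobase}\n#solvent={scale.solvent}\n")
        fh.write("residue\tdG_kJ_per_mol\n")
        for r, v in sorted(scale.entries.items()):
            fh.write(f"{r}\t{v:.4f}\n")


def read_scale_tsv(path) -> AffinityScale:
    meta = {}
    body = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if value:
                meta[key] = value
        else:
            body.append(line)
    df = pd.read_csv(StringIO("\n".join(body)), sep="\t")
    return AffinityScale(
        nucleobase=meta.get("nucleobase", "?"),
        solvent=meta.get("solvent", "?"),
        entries=dict(zip(df["residue"], df["dG_kJ_per_mol"])),
    )


def _read_packaged(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("basepref.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_reference_scale_table() -> pd.DataFrame:
    """Raw (partial) reference ΔG rows, including single-entry groups."""
    return _read_packaged("reference_scales.tsv")


def load_reference_scales() -> dict[tuple[str, str], AffinityScale]:
    """Partial reference scales keyed by (nucleobase, solvent).

    Groups with fewer than 2 transcribed entries cannot form a valid scale
    and are omitted; use ``load_reference_scale_table`` for the raw rows.
    """
    df = load_reference_scale_table()
    out = {}
    for (base, solvent), grp in df.groupby(["nucleobase", "solvent"]):
        if len(grp) < 2:
            continue
        out[(base, solvent)] = AffinityScale(
            nucleobase=base, solvent=solvent,
            entries=dict(zip(grp["residue"], grp["dG_kJ_per_mol"])),
        )
    return out


def load_reference_ddg() -> pd.DataFrame:
    """Prose-quoted reference ΔΔG values (first base minus second)."""
    return _read_packaged("reference_ddg.tsv")


def load_reference_statistics() -> pd.DataFrame:
    """Published ρ/RMSD pair statistics (not recomputable from the partial scales)."""
    return _read_packaged("reference_statistics.tsv")


def load_reference_replicate_sd() -> pd.DataFrame:
    """Published replicate SDs of ΔG over 5 independent repeats."""
    return _read_packaged("reference_replicate_sd.tsv")


def load_factor1() -> pd.Series:
    """Consensus Factor 1 hydrophobicity, residue (3-letter) → value."""
    df = _read_packaged("factor1_hydrophobicity.tsv")
    return pd.Series(df["factor1"].values, index=df["residue"].values, name="factor1")
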