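"""End-to-end orchestration: one config, one seed, one run directory.

A run executes the stages in dependency order — window generation → PMF →
binding ΔG → split-half convergence → interaction-mode occupancy →
affinity-scale comparison → toy-complex interface enrichment — and writes
every artifact under a single directory together with a manifest carrying
the config hash and seed, so a run is reproducible byte-for-byte from its
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from basepref import constants, convergence, enrichment, modes, pmf, scales
from basepref.models import PMFModel
from basepref.synthetic import (
    UmbrellaSeries,
    make_snapshot,
    make_toy_complex,
    write_series,
)
from basepref.synthetic.complexes import ToyComplexSpec
from basepref.synthetic.windows import subseed


@dataclass
class RunConfig:
    """Declarative pipeline configuration; defaults mirror the study setup."""

    temperature: float = constants.DEFAULT_T
    force_constant: float = constants.DEFAULT_FORCE_CONSTANT
    centers: tuple = constants.DEFAULT_CENTERS
    n_per_window: int = 10_000
    bin_width: float = constants.DEFAULT_BIN_WIDTH
    plateau: tuple = constants.DEFAULT_PLATEAU
    r_c: float | None = None                 # None -> plateau-onset policy
    v_standard: float = constants.V_STANDARD
    convergence_threshold: float = constants.CONVERGENCE_THRESHOLD
    extension_increment: int = 2000
    max_extension_rounds: int = 10
    replicate_sd_threshold: float = constants.REPLICATE_SD_THRESHOLD
    pi_occupancy_threshold: float = 0.5
    hbond_occupancy_threshold: float = 0.1
    outlier_cutoff: float = 1.0
    seed: int = 1
    model_family: str = "gaussian_well"
    model_epsilon: float = 8.0
    model_r0: float = 0.5
    model_sigma: float = 0.1
    snapshots_per_mode: int = 50

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("centers", "plateau"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["centers"] = list(d["centers"])
        d["plateau"] = list(d["plateau"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def model(self) -> PMFModel:
        return PMFModel(
            family=self.model_family, epsilon=self.model_epsilon,
            r0=self.model_r0, sigma=self.model_sigma,
        )


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "artifacts": [], "stages": []}

    def record(stage, *files):
        manifest["stages"].append(stage)
        manifest["artifacts"].extend(str(f.relative_to(out)) for f in files)

    model = config.model()
    settings = convergence.PMFSettings(
        bin_width=config.bin_width, temperature=config.temperature,
        plateau=tuple(config.plateau), r_c=config.r_c, v_standard=config.v_standard,
    )

    # 1. simulate
    series = UmbrellaSeries(
        model, centers=config.centers, force_constant=config.force_constant,
        n_initial=config.n_per_window, seed=subseed(config.seed, 0),
        temperature=config.temperature,
    )
    windows_dir = out / "windows"
    write_series(series.windows, windows_dir)
    record("simulate", windows_dir / "series.json")

    # 2-3. pmf + binding free energy
    fe, profile = pmf.estimate_dg(
        series.windows, bin_width=config.bin_width, temperature=config.temperature,
        plateau=tuple(config.plateau), r_c=config.r_c, v_standard=config.v_standard,
        nucleobase="synthetic", residue=model.family, solvent="model",
    )
    pmf_path = out / "pmf.tsv"
    pmf.write_pmf_tsv(profile, pmf_path)
    r_min, w_min = pmf.pmf_minimum(profile)
    oracle = pmf.oracle_free_energy(model, r_c=fe.r_c,
                                    v_standard=config.v_standard,
                                    temperature=config.temperature)
    fe_path = out / "free_energy.json"
    _dump_json({"dg_kJ_per_mol": fe.dg, "r_c_nm": fe.r_c,
                "dg_oracle_kJ_per_mol": oracle.dg,
                "abs_error_vs_oracle": abs(fe.dg - oracle.dg),
                "pmf_minimum_nm": r_min, "pmf_minimum_kJ_per_mol": w_min},
               fe_path)
    record("pmf", pmf_path, fe_path)

    # 4. convergence
    report = convergence.extend_until_converged(
        series, increment=config.extension_increment,
        max_rounds=config.max_extension_rounds, settings=settings,
        threshold=config.convergence_threshold,
    )
    conv_path = out / "convergence.json"
    _dump_json(report.to_dict(), conv_path)
    record("converge", conv_path)

    # 5. interaction modes at the PMF-minimum window
    idx = modes.window_at_minimum(config.centers, r_min)
    snap_seed = subseed(config.seed, 1)
    snapshots = []
    for i in range(config.snapshots_per_mode):
        snapshots.append(make_snapshot("stacking", seed=subseed(snap_seed, 2 * i)))
    for i in range(config.snapshots_per_mode // 2):
        snapshots.append(make_snapshot("none", seed=subseed(snap_seed, 2 * i + 1)))
    table = modes.occupancy_table(snapshots)
    table["window_index"] = idx
    modes_path = out / "modes.tsv"
    table.to_csv(modes_path, sep="\t", index=False)
    dom_path = out / "modes_dominant.tsv"
    modes.dominant_modes(
        table, pi_threshold=config.pi_occupancy_threshold,
        hbond_threshold=config.hbond_occupancy_threshold,
    ).to_csv(dom_path, sep="\t", index=False)
    record("modes", modes_path, dom_path)

    # 6. affinity-scale comparison on the packaged reference scales
    ref = scales.load_reference_scales()
    comp = scales.compare_report(ref[("5mC", "water")], ref[("5hmC", "water")],
                                 outlier_cutoff=config.outlier_cutoff)
    scales_path = out / "scales_comparison.json"
    _dump_json({"scale_a": "5mC(water)", "scale_b": "5hmC(water)",
                "residues": comp.residues, "spearman_rho": comp.spearman_rho,
                "rmsd_kJ_per_mol": comp.rmsd, "ddg": comp.ddg,
                "outliers": comp.outliers, "outlier_cutoff": comp.outlier_cutoff},
               scales_path)
    record("scales", scales_path)

    # 7. toy-complex enrichment
    residues = (("TRP", "interface"), ("ARG", "interface"),
                ("ASP", "surface"), ("SER", "surface"), ("GLY", "surface"))
    structures = []
    for base in ("5mC", "CYT"):
        text = make_toy_complex(ToyComplexSpec(residues=residues, base_type=base))
        structures.append(enrichment.parse_structure(text, name=f"toy_{base}"))
    report_df = enrichment.enrichment_report(structures)
    enr_path = out / "enrichment.tsv"
    report_df.to_csv(enr_path, sep="\t")
    record("enrich", enr_path)

    _dump_json(manifest, out / "manifest.json")
    return out


def report(run_dir) -> str:
    """Human-readable summary assembled from run artifacts (no recomputation)."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{run} is not a completed run (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"Run {run.name}  (config hash {manifest['config_hash']}, "
             f"seed {manifest['config']['seed']})", ""]

    fe = json.loads((run / "free_energy.json").read_text())
    lines += ["Binding free energy",
              f"  dG = {fe['dg_kJ_per_mol']:.3f} kJ/mol at r_c = {fe['r_c_nm']:.3f} nm "
              f"(oracle {fe['dg_oracle_kJ_per_mol']:.3f}, "
              f"|error| {fe['abs_error_vs_oracle']:.3f})",
              f"  PMF minimum {fe['pmf_minimum_kJ_per_mol']:.2f} kJ/mol "
              f"at {fe['pmf_minimum_nm']:.3f} nm", ""]

    conv = json.loads((run / "convergence.json").read_text())
    lines += ["Split-half convergence",
              f"  dG halves: {conv['dg_first_half']:.3f} / {conv['dg_second_half']:.3f} "
              f"kJ/mol (|diff| {conv['difference']:.3f}, threshold {conv['threshold']})",
              f"  converged: {conv['converged']} after "
              f"{conv['extensions_performed']} extension(s)", ""]

    modes_path = run / "modes.tsv"
    if modes_path.exists():
        tbl = pd.read_csv(modes_path, sep="\t")
        lines.append("Interaction-mode occupancy (PMF-minimum window)")
        for _, row in tbl.iterrows():
            lines.append(f"  {row['mode']:<10} {row['fraction']:.3f}  (n={row['n']})")
        lines.append("")

    scales_path = run / "scales_comparison.json"
    if scales_path.exists():
        sc = json.loads(scales_path.read_text())
        lines += ["Affinity-scale comparison "
                  f"{sc['scale_a']} vs {sc['scale_b']}",
                  f"  Spearman rho = {sc['spearman_rho']:.3f}, "
                  f"RMSD = {sc['rmsd_kJ_per_mol']:.3f} kJ/mol",
                  f"  outliers (|ddG| > {sc['outlier_cutoff']}): "
                  f"{', '.join(sc['outliers']) or 'none'}", ""]

    enr_path = run / "enrichment.tsv"
    if enr_path.exists():
        df = pd.read_csv(enr_path, sep="\t", index_col=0)
        present = df[df["E_5mC"].fillna(0) + df["E_CYT"].fillna(0) > 0]
        lines.append("Interface enrichment (toy complexes)")
        for aa, row in present.iterrows():
            proxy = f"{row['proxy']:.3f}" if np.isfinite(row["proxy"]) else "NA"
            lines.append(f"  {aa:<4} E(5mC)={row['E_5mC']:.3f} "
                         f"E(CYT)={row['E_CYT']:.3f} proxy={proxy}")
    else:
        lines.append("Interface enrichment: skipped (no inputs)")
    return "\n".join(lines) + "\n"
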