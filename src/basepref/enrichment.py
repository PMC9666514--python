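"""Amino-acid enrichment at 5mC/CYT nucleobase interfaces in PDB complexes.

For a set of protein/nucleic-acid complexes containing 5-methylcytosine
(residue names 5CM/5MC) and/or cytosine (DC/C), the per-amino-acid
enrichment is

    E(aa) = (aa's fraction of interface surface area)
          / (aa's fraction of whole protein surface area),

with areas pooled over all structures before the ratio is taken. Interface
residues are those with at least one heavy atom in van-der-Waals contact
(r_i + r_j + 0.5 Å, inclusive) with a nucleobase heavy atom. Solvent
accessible surface areas are Shrake–Rupley (probe 1.4 Å, 960 points/atom,
Bondi radii) computed on the protein chains alone — the nucleic acid is
removed, so "surface" means the protein surface.

The relative preference of an amino acid for 5mC over CYT is summarized by
the statistical free-energy proxy −ln(E(5mC)/E(CYT)): negative values mean
preference for 5mC, matching the ΔΔG sign convention. The proxy is compared
against the consensus Factor 1 hydrophobicity scale, optionally after
averaging within physicochemical groups.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from scipy import stats

from basepref.errors import NoNucleobaseError
from basepref.scales import load_factor1

#: Bondi van-der-Waals radii, Å.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Residue-name aliases for nucleobase site recognition (configurable).
FIVE_MC_ALIASES = ("5CM", "5MC")
CYT_ALIASES = ("DC", "C")

AA3_TO_TITLE = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}
AMINO_ACIDS = sorted(AA3_TO_TITLE.values())

#: Physicochemical grouping used for the grouped hydrophobicity correlation.
GROUPS = {
    "apolar": ["Ala", "Cys", "Ile", "Leu", "Met", "Val"],
    "aromatic": ["Phe", "Trp", "Tyr", "His"],
    "OH-containing": ["Ser", "Thr"],
    "amide-containing": ["Asn", "Gln"],
    "positively charged": ["Arg", "Lys"],
    "negatively charged": ["Asp", "Glu"],
    "Gly": ["Gly"],
    "Pro": ["Pro"],
}


@dataclass
class StructureComplex:
    """A parsed complex: Bio.PDB model plus site/protein bookkeeping."""

    model: object                       # Bio.PDB Model (hydrogens ignored downstream)
    sites: list[tuple[str, object]]     # (base type "5mC"/"CYT", Residue)
    protein_residues: list[object]      # Bio.PDB Residues with standard aa names
    name: str = ""

    def site_types(self) -> set[str]:
        return {t for t, _ in self.sites}


def _resolve_altlocs(model) -> None:
    """Keep the highest-occupancy altloc (ties → first label)."""
    for residue in model.get_residues():
        for atom in list(residue):
            if atom.is_disordered():
                children = sorted(
                    atom.child_dict.items(),
                    key=lambda kv: (-(kv[1].get_occupancy() or 0.0), kv[0]),
                )
                atom.disordered_select(children[0][0])


def parse_structure(
    pdb_text: str,
    name: str = "",
    mc_aliases=FIVE_MC_ALIASES,
    cyt_aliases=CYT_ALIASES,
) -> StructureComplex:
    """Parse PDB text into a StructureComplex.

    Raises NoNucleobaseError when neither a 5mC nor a CYT site is present,
    and ValueError (with the parser's line context) on malformed records.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(name or "complex", io.StringIO(pdb_text))
    except Exception as exc:
        raise ValueError(f"unparseable PDB record: {exc}") from exc
    model = next(structure.get_models())
    _resolve_altlocs(model)
    sites, protein = [], []
    for residue in model.get_residues():
        resname = residue.get_resname().strip().upper()
        if resname in mc_aliases:
            sites.append(("5mC", residue))
        elif resname in cyt_aliases:
            sites.append(("CYT", residue))
        elif resname in AA3_TO_TITLE:
            protein.append(residue)
    if not sites:
        raise NoNucleobaseError("no 5mC or CYT nucleobase site found")
    return StructureComplex(model=model, sites=sites, protein_residues=protein, name=name)


def _heavy_atoms(residue):
    out = []
    for a in residue.get_atoms():
        elem = (a.element or "").strip().upper()
        if not elem:
            elem = "H" if a.get_name().strip().startswith("H") else "C"
        if elem not in ("H", "D"):
            out.append(a)
    return out


def _res_key(residue) -> tuple:
    """(chain id, residue id) — stable across copied models."""
    return (residue.get_parent().id, residue.id)


def _radius(atom) -> float:
    elem = (atom.element or "").upper()
    if elem not in VDW_RADII:
        raise KeyError(f"no van-der-Waals radius configured for element {elem!r}")
    return VDW_RADII[elem]


def _protein_only_copy(sc: StructureComplex):
    """Copy of the model holding only protein heavy atoms."""
    keep = {_res_key(r) for r in sc.protein_residues}
    model = sc.model.copy()
    for chain in list(model):
        for residue in list(chain):
            if (chain.id, residue.id) not in keep:
                chain.detach_child(residue.id)
                continue
            for atom in list(residue):
                elem = (atom.element or "").strip().upper()
                if elem in ("H", "D") or (not elem and atom.get_name().startswith("H")):
                    residue.detach_child(atom.id)
        if len(chain) == 0:
            model.detach_child(chain.id)
    return model


def sasa(
    sc: StructureComplex,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[tuple, float]:
    """Per-residue SASA (Å²) of the protein in protein-only context.

    Returns {(chain id, residue id): area}. Deterministic (fixed
    Shrake–Rupley point set); nucleic-acid atoms and hydrogens are excluded
    from the context entirely.
    """
    for residue in sc.protein_residues:
        for atom in _heavy_atoms(residue):
            _radius(atom)  # fail early on unconfigured elements
    stripped = _protein_only_copy(sc)
    if not any(True for _ in stripped.get_atoms()):
        return {}
    sr = ShrakeRupley(probe_radius=probe, n_points=n_points, radii_dict=VDW_RADII)
    sr.compute(stripped, level="R")
    return {(chain.id, residue.id): float(residue.sasa)
            for chain in stripped for residue in chain}


def interface_residues(sc: StructureComplex, site, tol: float = 0.5) -> list:
    """Protein residues with ≥1 heavy atom in vdW contact with the site."""
    site_atoms = _heavy_atoms(site)
    s_coords = np.array([a.coord for a in site_atoms], dtype=float)
    s_radii = np.array([_radius(a) for a in site_atoms], dtype=float)
    out = []
    for residue in sc.protein_residues:
        hit = False
        for atom in _heavy_atoms(residue):
            d = np.linalg.norm(s_coords - np.asarray(atom.coord, dtype=float), axis=1)
            if np.any(d <= s_radii + _radius(atom) + tol):
                hit = True
                break
        if hit:
            out.append(residue)
    return out


def enrichment(
    structures: list[StructureComplex],
    base_type: str,
    tol: float = 0.5,
    probe: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Pooled per-amino-acid enrichment table for one nucleobase type.

    Areas are summed over all structures before ratios are taken. Amino
    acids absent from every interface get E = 0; amino acids absent from
    every surface get E = NaN. A structure without ``base_type`` sites
    contributes only to the surface (denominator) totals.
    """
    if not any(base_type in sc.site_types() for sc in structures):
        raise ValueError(f"no structure contains a {base_type} site")
    area_int = pd.Series(0.0, index=AMINO_ACIDS)
    area_surf = pd.Series(0.0, index=AMINO_ACIDS)
    n_structs = 0
    for sc in structures:
        areas = sasa(sc, probe=probe, n_points=n_points)
        for residue in sc.protein_residues:
            aa = AA3_TO_TITLE[residue.get_resname().strip().upper()]
            area_surf[aa] += areas.get(_res_key(residue), 0.0)
        iface: dict[tuple, object] = {}
        for site_type, site in sc.sites:
            if site_type != base_type:
                continue
            for residue in interface_residues(sc, site, tol=tol):
                iface[_res_key(residue)] = residue
        for key, residue in iface.items():
            aa = AA3_TO_TITLE[residue.get_resname().strip().upper()]
            area_int[aa] += areas.get(key, 0.0)
        n_structs += 1
    total_surf = area_surf.sum()
    if total_surf <= 0:
        raise ValueError("zero total protein surface area")
    frac_surf = area_surf / total_surf
    total_int = area_int.sum()
    frac_int = area_int / total_int if total_int > 0 else area_int * 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(frac_surf > 0, frac_int / frac_surf, np.nan)
    table = pd.DataFrame({
        "area_interface": area_int, "area_surface": area_surf,
        "frac_interface": frac_int, "frac_surface": frac_surf, "E": e,
    })
    table.attrs["base_type"] = base_type
    table.attrs["structure_count"] = n_structs
    return table


def preference_proxy(e5mc: pd.DataFrame, ecyt: pd.DataFrame) -> pd.Series:
    """−ln(E(5mC)/E(CYT)) per amino acid; NaN (missing) where either E ≤ 0."""
    e1, e2 = e5mc["E"], ecyt["E"]
    with np.errstate(divide="ignore", invalid="ignore"):
        proxy = -np.log(e1 / e2)
    proxy = proxy.where((e1 > 0) & (e2 > 0))
    proxy.name = "proxy"
    return proxy


def enrichment_report(
    structures: list[StructureComplex], **kwargs
) -> pd.DataFrame:
    """Combined table: E for both bases plus the preference proxy."""
    e5 = enrichment(structures, "5mC", **kwargs)
    ec = enrichment(structures, "CYT", **kwargs)
    return pd.DataFrame({
        "E_5mC": e5["E"], "E_CYT": ec["E"],
        "proxy": preference_proxy(e5, ec),
        "area_interface_5mC": e5["area_interface"],
        "area_interface_CYT": ec["area_interface"],
        "area_surface": e5["area_surface"],
    })


def correlate_hydrophobicity(
    proxy: pd.Series,
    factor1: pd.Series | None = None,
    grouped: bool = False,
) -> dict:
    """Pearson correlation of the preference proxy with Factor 1.

    Grouped mode averages the proxy and Factor 1 within the physicochemical
    groups first (groups with no data are dropped). Returns r, R², the
    two-sided t-distribution p-value, n, and the paired data used.
    """
    if factor1 is None:
        factor1 = load_factor1()
    paired = pd.DataFrame({"proxy": proxy, "factor1": factor1}).dropna()
    if grouped:
        rows = []
        for gname, members in GROUPS.items():
            sub = paired.loc[[m for m in members if m in paired.index]]
            if len(sub):
                rows.append({"group": gname, "proxy": sub["proxy"].mean(),
                             "factor1": sub["factor1"].mean()})
        paired = pd.DataFrame(rows).set_index("group")
    if len(paired) < 3:
        raise ValueError("need at least 3 paired points")
    if paired["proxy"].std() == 0 or paired["factor1"].std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(paired["factor1"], paired["proxy"])
    return {"r": float(r), "r2": float(r**2), "p_value": float(p),
            "n": int(len(paired)), "data": paired}
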