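"""PDB parsing, SASA, interface detection and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from basepref import enrichment as en
from basepref.errors import LayoutError, NoNucleobaseError
from basepref.synthetic import ToyComplexSpec, make_toy_complex
from conftest import mc_sasa

ISOLATED_CARBON_AREA = 4 * np.pi * (1.7 + 1.4) ** 2  # ~120.76 A^2


def _toy(residues, base="5mC"):
    return en.parse_structure(make_toy_complex(ToyComplexSpec(residues=residues, base_type=base)))


# -------------------------------------------------------------------- parsing

def test_toy_complex_round_trips_with_one_site():
    sc = _toy((("ARG", "interface"),))
    assert [t for t, _ in sc.sites] == ["5mC"]
    contacts = en.interface_residues(sc, sc.sites[0][1])
    assert [r.get_resname() for r in contacts] == ["ARG"]


def test_cytosine_complex_recognized_as_cyt():
    sc = _toy((("ALA", "surface"),), base="CYT")
    assert sc.site_types() == {"CYT"}


def test_protein_only_file_raises_no_nucleobase():
    text = make_toy_complex(ToyComplexSpec(residues=(("ALA", "surface"),)))
    protein_only = "\n".join(l for l in text.splitlines() if " 5CM " not in l)
    with pytest.raises(NoNucleobaseError):
        en.parse_structure(protein_only)


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60 10.00           C
HETATM    3  N1  5CM B   1       0.000   0.000   5.000  1.00 10.00           N
END
"""


def test_altloc_resolved_to_highest_occupancy():
    sc = en.parse_structure(ALTLOC_PDB)
    atom = next(iter(sc.protein_residues[0].get_atoms()))
    assert atom.coord[0] == pytest.approx(9.0)  # altloc B, occupancy 0.60

    tie = ALTLOC_PDB.replace("0.40", "0.60")
    atom = next(iter(en.parse_structure(tie).protein_residues[0].get_atoms()))
    assert atom.coord[0] == pytest.approx(0.0)  # tie -> first label (A)


# ----------------------------------------------------------------------- SASA

def test_isolated_carbon_sphere_area():
    sc = _toy((("GLY", "surface"),))
    areas = en.sasa(sc)
    assert list(areas.values())[0] == pytest.approx(ISOLATED_CARBON_AREA, rel=1e-6)


def test_caged_atom_has_zero_area():
    sc = _toy((("LYS", "buried"),))
    areas = en.sasa(sc)
    lys = [r for r in sc.protein_residues if r.get_resname() == "LYS"][0]
    assert areas[en._res_key(lys)] == 0.0


def test_two_atom_overlap_matches_monte_carlo_oracle():
    # two interface residues 4.16 A apart: expanded spheres overlap
    sc = _toy((("ALA", "interface"), ("VAL", "interface"), ("GLY", "interface")))
    coords, keys = [], []
    for r in sc.protein_residues:
        a = next(iter(r.get_atoms()))
        coords.append(a.coord)
        keys.append(en._res_key(r))
    areas = en.sasa(sc)
    oracle = mc_sasa(coords, [1.7] * len(coords), n_points=300_000, seed=4)
    for key, ref in zip(keys, oracle):
        assert areas[key] == pytest.approx(ref, rel=0.02)


# ------------------------------------------------------------------ interface

def test_distant_residues_are_not_interface():
    sc = _toy((("ALA", "surface"), ("TRP", "surface")))
    assert en.interface_residues(sc, sc.sites[0][1]) == []


def test_contact_boundary_is_inclusive():
    # CA carbon exactly at r_C + r_N + tol = 1.7 + 1.55 + 0.5 from the N1 atom
    base = "HETATM    2  N1  5CM B   1       0.000   0.000   0.000  1.00  0.00           N\n"
    ca = "ATOM      1  CA  ALA A   1       0.000   0.000   3.750  1.00  0.00           C\n"
    sc = en.parse_structure(ca + base + "END\n")
    assert len(en.interface_residues(sc, sc.sites[0][1])) == 1
    ca_out = ca.replace("3.750", "3.751")
    sc = en.parse_structure(ca_out + base + "END\n")
    assert en.interface_residues(sc, sc.sites[0][1]) == []


def test_buried_only_spec_gives_empty_interface():
    sc = _toy((("LYS", "buried"), ("MET", "buried")))
    assert en.interface_residues(sc, sc.sites[0][1]) == []


def test_overfull_interface_is_a_layout_error():
    with pytest.raises(LayoutError):
        make_toy_complex(ToyComplexSpec(residues=((("ALA", "interface"),) * 16)))


# ----------------------------------------------------------------- enrichment

def test_uniform_composition_gives_unit_enrichment_and_zero_proxy():
    residues = (("TRP", "interface"), ("ASP", "interface"),
                ("TRP", "surface"), ("ASP", "surface"))
    structures = [_toy(residues, base=b) for b in ("5mC", "CYT")]
    e5 = en.enrichment(structures, "5mC")
    ec = en.enrichment(structures, "CYT")
    for tbl in (e5, ec):
        present = tbl[tbl["area_surface"] > 0]
        assert np.allclose(present["E"], 1.0)
        assert tbl["frac_interface"].sum() == pytest.approx(1.0)
        assert tbl["frac_surface"].sum() == pytest.approx(1.0)
    proxy = en.preference_proxy(e5, ec).dropna()
    assert np.allclose(proxy, 0.0, atol=1e-12)


def test_sole_interface_residue_enrichment_equals_inverse_surface_share():
    # interface = 1 Trp; surface composition 10% Trp by area (10 equal CAs)
    residues = (("TRP", "interface"),) + tuple(("LEU", "surface") for _ in range(9))
    sc = _toy(residues)
    table = en.enrichment([sc], "5mC")
    assert table.loc["Trp", "E"] == pytest.approx(10.0, rel=0.02)


def test_planted_composition_recovered_within_sasa_tolerance():
    residues = (("TRP", "interface"), ("ALA", "interface"),
                ("ASP", "interface"), ("SER", "interface"),
                ("TRP", "surface"), ("GLY", "surface"),
                ("LEU", "surface"), ("LYS", "surface"))
    sc = _toy(residues)
    table = en.enrichment([sc], "5mC")
    # analytic E from Monte-Carlo reference areas of the same layout
    coords, radii, names, placement = [], [], [], []
    for (name, place), r in zip(residues, sc.protein_residues):
        a = next(iter(r.get_atoms()))
        coords.append(a.coord)
        radii.append(1.7)
        names.append(en.AA3_TO_TITLE[name])
        placement.append(place)
    ref_areas = mc_sasa(coords, radii, n_points=100_000, seed=9)
    surf = pd.Series(0.0, index=en.AMINO_ACIDS)
    iface = pd.Series(0.0, index=en.AMINO_ACIDS)
    for aa, place, area in zip(names, placement, ref_areas):
        surf[aa] += area
        if place == "interface":
            iface[aa] += area
    expected_e = (iface / iface.sum()) / (surf / surf.sum())
    for aa in expected_e.dropna().index:
        assert table.loc[aa, "E"] == pytest.approx(expected_e[aa], rel=0.02)


def test_structure_without_base_type_feeds_only_denominator():
    with_site = _toy((("TRP", "interface"), ("LEU", "surface")))
    cyt_only = _toy((("TRP", "surface"), ("LEU", "surface")), base="CYT")
    table = en.enrichment([with_site, cyt_only], "5mC")
    assert table.attrs["structure_count"] == 2
    # Trp interface area comes from structure 1 only; surface from both.
    assert table.loc["Trp", "area_interface"] < table.loc["Trp", "area_surface"]


def test_moving_a_residue_into_contact_never_decreases_its_enrichment():
    # Same residue set (surface composition fixed), one more Trp in contact.
    small = _toy((("TRP", "interface"), ("ALA", "interface"),
                  ("TRP", "surface"), ("LEU", "surface")))
    big = _toy((("TRP", "interface"), ("ALA", "interface"),
                ("TRP", "interface"), ("LEU", "surface")))
    e_small = en.enrichment([small], "5mC").loc["Trp", "E"]
    e_big = en.enrichment([big], "5mC").loc["Trp", "E"]
    assert e_big >= e_small


# ---------------------------------------------------------------------- proxy

def test_preference_proxy_values_and_missingness():
    idx = ["Ala", "Arg"]
    e5 = pd.DataFrame({"E": [2.0, 1.0]}, index=idx)
    ec = pd.DataFrame({"E": [1.0, 0.0]}, index=idx)
    proxy = en.preference_proxy(e5, ec)
    assert proxy["Ala"] == pytest.approx(-np.log(2.0))
    assert np.isnan(proxy["Arg"])  # E(CYT) = 0 -> missing, never 0


# ---------------------------------------------------------------- correlation

def test_hydrophobicity_correlation_limits():
    f1 = en.load_factor1()
    exact = 0.5 * f1 + 1.0
    res = en.correlate_hydrophobicity(exact)
    assert res["r2"] == pytest.approx(1.0)
    anti = en.correlate_hydrophobicity(-f1)
    assert anti["r"] == pytest.approx(-1.0)


def test_hydrophobicity_correlation_hand_computed():
    proxy = pd.Series({"Ala": 0.2, "Arg": -0.4, "Asp": 0.9, "Trp": -0.1})
    f1 = en.load_factor1()
    x = f1[proxy.index].to_numpy()
    y = proxy.to_numpy()
    r_hand = (((x - x.mean()) * (y - y.mean())).sum()
              / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    res = en.correlate_hydrophobicity(proxy)
    assert res["r"] == pytest.approx(r_hand)
    assert res["n"] == 4


def test_grouped_correlation_averages_within_groups():
    proxy = pd.Series({"Ala": 1.0, "Val": 3.0, "Asp": -1.0, "Glu": -3.0,
                       "Ser": 0.5, "Thr": 1.5})
    res = en.correlate_hydrophobicity(proxy, grouped=True)
    data = res["data"]
    assert data.loc["apolar", "proxy"] == pytest.approx(2.0)
    assert data.loc["negatively charged", "proxy"] == pytest.approx(-2.0)
    assert res["n"] == 3


def test_factor1_fixture_covers_all_twenty():
    f1 = en.load_factor1()
    assert len(f1) == 20
    groups = [aa for members in en.GROUPS.values() for aa in members]
    assert sorted(groups) == sorted(f1.index)
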