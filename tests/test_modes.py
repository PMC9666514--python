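"""Interaction-mode detectors, occupancy aggregation and threshold wording."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from basepref import modes
from basepref.errors import GeometryError, InconsistentFixtureError
from basepref.modes import DEFAULT_CRITERIA, GeometricCriteria
from basepref.snapshot import (
    Atom,
    InteractionSnapshot,
    read_snapshots,
    write_snapshots,
)
from basepref.synthetic import make_snapshot

ALL_MODES = ("stacking", "cation_pi", "anion_pi", "hbond", "none")


def _hexagon(center, mol, tilt=0.0, ring_id=0):
    ang = np.arange(6) * np.pi / 3
    pts = np.stack([0.139 * np.cos(ang), 0.139 * np.sin(ang), np.zeros(6)], axis=1)
    if tilt:
        rot = Rotation.from_euler("x", tilt, degrees=True).as_matrix()
        pts = pts @ rot.T
    return [Atom("C", tuple(p + np.asarray(center)), mol=mol, ring_id=ring_id) for p in pts]


# ------------------------------------------------------------- label recovery

@pytest.mark.parametrize("mode", ALL_MODES)
def test_classifier_recovers_planted_labels_perfectly(mode):
    for i in range(200):
        snap = make_snapshot(mode, seed=1000 + i)
        fired = modes.classify(snap)
        if mode == "none":
            assert fired == set()
        else:
            assert mode in fired


# ------------------------------------------------ geometry and boundary rules

def test_stacking_boundary_is_inclusive():
    c = DEFAULT_CRITERIA
    atoms = _hexagon((0, 0, 0), "base") + _hexagon((0, 0, c.stacking_max_distance), "sidechain")
    snap = InteractionSnapshot(atoms)
    assert modes.detect_stacking(snap)
    atoms = _hexagon((0, 0, 0), "base") + _hexagon((0, 0, c.stacking_max_distance + 1e-6), "sidechain")
    assert not modes.detect_stacking(InteractionSnapshot(atoms))


def test_perpendicular_rings_do_not_stack():
    atoms = _hexagon((0, 0, 0), "base") + _hexagon((0, 0, 0.35), "sidechain", tilt=90.0)
    assert not modes.detect_stacking(InteractionSnapshot(atoms))


def test_small_ring_is_a_geometry_error():
    atoms = _hexagon((0, 0, 0), "base")
    atoms += [Atom("C", (0.1 * i, 0, 0.35), mol="sidechain", ring_id=0) for i in range(2)]
    with pytest.raises(GeometryError):
        modes.detect_stacking(InteractionSnapshot(atoms))


def test_ion_pi_axial_vs_in_plane():
    base = _hexagon((0, 0, 0), "base")
    axial = base + [Atom("N", (0, 0, 0.40), mol="sidechain", charge_class="cation")]
    assert modes.detect_ion_pi(InteractionSnapshot(axial)) == "cation_pi"
    in_plane = base + [Atom("O", (0.40, 0, 0), mol="sidechain", charge_class="anion")]
    assert modes.detect_ion_pi(InteractionSnapshot(in_plane)) == "none"
    neutral = base + [Atom("N", (0, 0, 0.40), mol="sidechain")]
    assert modes.detect_ion_pi(InteractionSnapshot(neutral)) == "none"


def test_cation_pi_wins_the_tie():
    atoms = _hexagon((0, 0, 0), "base")
    atoms.append(Atom("N", (0, 0, 0.40), mol="sidechain", charge_class="cation"))
    atoms.append(Atom("O", (0, 0, -0.40), mol="sidechain", charge_class="anion"))
    assert modes.detect_ion_pi(InteractionSnapshot(atoms)) == "cation_pi"


def _hbond_atoms(da=0.28, second_acceptor=None):
    atoms = [Atom("O", (0.0, 0.0, 0.0), mol="base", is_acceptor=True)]
    if second_acceptor is not None:
        atoms.append(Atom("O", second_acceptor, mol="base", is_acceptor=True))
    atoms.append(Atom("N", (da, 0.0, 0.0), mol="sidechain", is_donor=True))
    d_idx = len(atoms) - 1
    atoms.append(Atom("H", (da - 0.1, 0.0, 0.0), mol="sidechain", is_h=True, bonded_to=d_idx))
    return atoms


def test_linear_hbond_detected_and_long_one_rejected():
    assert len(modes.detect_hbonds(InteractionSnapshot(_hbond_atoms(0.28)))) == 1
    assert len(modes.detect_hbonds(InteractionSnapshot(_hbond_atoms(0.40)))) == 0


def test_two_acceptors_in_range_give_two_records():
    # second acceptor placed symmetrically, still within distance/angle cuts
    atoms = _hbond_atoms(0.30, second_acceptor=(0.0, 0.02, 0.0))
    bonds = modes.detect_hbonds(InteractionSnapshot(atoms))
    assert len(bonds) == 2


def test_hydrogen_without_donor_assignment_errors():
    atoms = [Atom("O", (0, 0, 0), mol="base", is_acceptor=True),
             Atom("H", (0.2, 0, 0), mol="sidechain", is_h=True)]
    with pytest.raises(GeometryError):
        modes.detect_hbonds(InteractionSnapshot(atoms))


def test_intramolecular_pairs_are_excluded():
    atoms = [Atom("O", (0.0, 0.0, 0.0), mol="sidechain", is_acceptor=True),
             Atom("N", (0.28, 0.0, 0.0), mol="sidechain", is_donor=True)]
    atoms.append(Atom("H", (0.18, 0.0, 0.0), mol="sidechain", is_h=True, bonded_to=1))
    assert modes.detect_hbonds(InteractionSnapshot(atoms)) == []


# -------------------------------------------------------- rigid-body symmetry

@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_detectors_invariant_under_rigid_transforms(seed):
    rng = np.random.default_rng(seed)
    snap = make_snapshot(ALL_MODES[seed % 5], seed=seed)
    rot = Rotation.random(rng=rng).as_matrix()
    moved = snap.transformed(rot, rng.uniform(-5, 5, 3))
    assert modes.classify(snap) == modes.classify(moved)


# ----------------------------------------------------------------- occupancy

def test_occupancy_counts_firing_fraction():
    snaps = [make_snapshot("stacking", seed=i) for i in range(6)]
    snaps += [make_snapshot("none", seed=100 + i) for i in range(4)]
    assert modes.occupancy(snaps, "stacking") == pytest.approx(0.6)
    assert modes.occupancy(snaps, "hbond") == 0.0
    with pytest.raises(ValueError):
        modes.occupancy([], "stacking")


def test_mixture_occupancy_within_binomial_ci():
    # 70% stacking poses with randomized geometry, n = 200, seed 3
    rng = np.random.default_rng(3)
    snaps = []
    for i in range(200):
        if i < 140:
            sep = rng.uniform(0.30, 0.44)
            ang = rng.uniform(0.0, 25.0)
            snaps.append(make_snapshot("stacking", seed=3000 + i, separation=sep, angle=ang))
        else:
            snaps.append(make_snapshot("none", seed=3000 + i))
    frac = modes.occupancy(snaps, "stacking")
    half_width = 2.576 * np.sqrt(0.7 * 0.3 / 200)
    assert abs(frac - 0.7) <= half_width


def test_occupancy_monotone_under_tighter_cutoffs():
    snaps = [make_snapshot("stacking", seed=i, separation=0.30 + 0.01 * (i % 15))
             for i in range(30)]
    loose = modes.occupancy(snaps, "stacking", DEFAULT_CRITERIA)
    tight = modes.occupancy(
        snaps, "stacking",
        GeometricCriteria(stacking_max_distance=0.36, stacking_max_angle=15.0))
    assert 0.0 <= tight <= loose <= 1.0


def test_dominant_mode_thresholds_follow_the_stated_wording():
    table = pd.DataFrame([
        {"pair": "p", "solvent": "water", "mode": "stacking", "fraction": 0.50, "n": 100},
        {"pair": "p", "solvent": "water", "mode": "stacking", "fraction": 0.49, "n": 100},
        {"pair": "p", "solvent": "water", "mode": "hbond", "fraction": 0.10, "n": 100},
        {"pair": "p", "solvent": "water", "mode": "hbond", "fraction": 0.101, "n": 100},
    ])
    kept = modes.dominant_modes(table)
    # "50% of time or more" keeps the 0.50 row; "more than 10%" drops 0.10.
    assert list(kept["fraction"]) == [0.50, 0.101]
    assert modes.dominant_modes(table.iloc[0:0]).empty


def test_window_nearest_pmf_minimum():
    centers = np.round(np.arange(0.4, 1.95, 0.1), 10)
    assert modes.window_at_minimum(centers, 0.52) == 1
    assert modes.window_at_minimum(centers, 0.44) == 0


# ------------------------------------------------------------------- fixtures

def test_inconsistent_fixture_geometry_is_rejected():
    with pytest.raises(InconsistentFixtureError):
        make_snapshot("stacking", separation=0.60)
    with pytest.raises(InconsistentFixtureError):
        make_snapshot("hbond", separation=0.45)
    with pytest.raises(InconsistentFixtureError):
        make_snapshot("none", separation=0.35)


def test_snapshot_json_round_trip_preserves_classification(tmp_path):
    snaps = [make_snapshot(m, seed=7) for m in ALL_MODES]
    path = tmp_path / "snaps.json"
    write_snapshots(snaps, path)
    loaded = read_snapshots(path)
    for orig, back in zip(snaps, loaded):
        assert back.true_mode == orig.true_mode
        assert modes.classify(back) == modes.classify(orig)


def test_snapshot_invariants_hold_for_generated_fixtures():
    for mode in ALL_MODES:
        snap = make_snapshot(mode, seed=11)
        snap.validate()  # ring size/coplanarity, H-donor bookkeeping
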