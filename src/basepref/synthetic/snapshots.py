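"""Labeled interaction poses for classifier testing.

Builds idealized planar six-membered rings and minimal donor/acceptor or
charged-group geometry so that each snapshot satisfies exactly the requested
interaction mode under the default geometric criteria (or none of them).
Idealized rather than chemically exact geometry is deliberate: the
classifiers must not depend on the fine structure of a real nucleobase.

Every snapshot is given a random rigid-body pose derived from the seed, so
fixtures also exercise rotation/translation invariance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from basepref import modes as modes_mod
from basepref.errors import InconsistentFixtureError
from basepref.modes import DEFAULT_CRITERIA, GeometricCriteria
from basepref.snapshot import Atom, InteractionSnapshot

MODES = ("stacking", "cation_pi", "anion_pi", "hbond", "none")

#: Circumradius of the idealized aromatic ring, nm (~1.39 Å bonds).
RING_RADIUS = 0.139


def _hexagon(center, normal_tilt_deg: float = 0.0, mol: str = "base", ring_id: int = 0):
    """Six carbon atoms of a planar hexagon, optionally tilted about x."""
    ang = np.arange(6) * np.pi / 3.0
    pts = np.stack([RING_RADIUS * np.cos(ang), RING_RADIUS * np.sin(ang), np.zeros(6)], axis=1)
    if normal_tilt_deg:
        rot = Rotation.from_euler("x", normal_tilt_deg, degrees=True).as_matrix()
        pts = pts @ rot.T
    pts = pts + np.asarray(center, dtype=float)
    return [Atom("C", tuple(p), mol=mol, ring_id=ring_id) for p in pts]


def _place_h_for_angle(d_xyz, a_xyz, dha_deg: float, dh: float = 0.1) -> np.ndarray:
    """Place H covalently on D so the D-H...A angle equals ``dha_deg``."""
    d_xyz = np.asarray(d_xyz, float)
    a_xyz = np.asarray(a_xyz, float)
    u = a_xyz - d_xyz
    u /= np.linalg.norm(u)
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-8:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)

    def angle_at_h(gamma):
        h = d_xyz + dh * (np.cos(gamma) * u + np.sin(gamma) * v)
        w1, w2 = d_xyz - h, a_xyz - h
        c = np.dot(w1, w2) / (np.linalg.norm(w1) * np.linalg.norm(w2))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    lo, hi = 0.0, np.pi * 0.999  # angle_at_h decreases monotonically in gamma
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_at_h(mid) > dha_deg:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)
    return d_xyz + dh * (np.cos(gamma) * u + np.sin(gamma) * v)


def make_snapshot(
    mode: str,
    seed: int = 0,
    separation: float | None = None,
    angle: float | None = None,
    criteria: GeometricCriteria = DEFAULT_CRITERIA,
    base_name: str = "5mC",
    residue_name: str = "X",
    solvent: str = "water",
) -> InteractionSnapshot:
    """Build a snapshot whose true label is ``mode`` under ``criteria``.

    Parameters
    ----------
    mode
        ``stacking`` | ``cation_pi`` | ``anion_pi`` | ``hbond`` | ``none``.
    separation
        Mode-specific key distance in nm: ring-centroid separation
        (stacking/none), charge-to-ring-centroid distance (ion–π), or
        donor–acceptor distance (hbond). Defaults: 0.35 / 0.40 / 0.28 /
        1.5 (none).
    angle
        Interplanar angle (stacking), angle from the ring normal (ion–π),
        or D–H···A angle (hbond), in degrees.

    Raises
    ------
    InconsistentFixtureError
        If the requested geometry does not realize the requested mode under
        ``criteria`` (or, for ``none``, if any detector fires).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    defaults = {"stacking": (0.35, 0.0), "cation_pi": (0.40, 0.0),
                "anion_pi": (0.40, 0.0), "hbond": (0.28, 180.0), "none": (1.5, 0.0)}
    sep0, ang0 = defaults[mode]
    sep = sep0 if separation is None else float(separation)
    ang = ang0 if angle is None else float(angle)
    if not (0.05 <= sep <= 2.0):
        raise ValueError("separation outside physical range 0.05-2.0 nm")

    atoms: list[Atom] = list(_hexagon((0, 0, 0), mol="base"))
    # Ring-edge acceptor (carbonyl-like oxygen) on the base.
    atoms.append(Atom("O", (0.25, 0.0, 0.0), mol="base", is_acceptor=True))

    if mode in ("stacking", "none"):
        atoms += _hexagon((0, 0, sep), normal_tilt_deg=ang, mol="sidechain")
    elif mode in ("cation_pi", "anion_pi"):
        a = np.radians(ang)
        pos = sep * np.array([np.sin(a), 0.0, np.cos(a)])
        elem, cls = ("N", "cation") if mode == "cation_pi" else ("O", "anion")
        atoms.append(Atom(elem, tuple(pos), mol="sidechain", charge_class=cls))
    elif mode == "hbond":
        acceptor = np.array([0.25, 0.0, 0.0])
        d_xyz = acceptor + np.array([sep, 0.0, 0.0])
        atoms.append(Atom("O", tuple(d_xyz), mol="sidechain", is_donor=True))
        d_idx = len(atoms) - 1
        h_xyz = _place_h_for_angle(d_xyz, acceptor, ang)
        atoms.append(Atom("H", tuple(h_xyz), mol="sidechain", is_h=True, bonded_to=d_idx))

    snap = InteractionSnapshot(
        atoms=atoms, base_name=base_name, residue_name=residue_name,
        solvent=solvent, true_mode=mode,
    )

    # Random rigid pose so fixtures do not share a privileged frame.
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    snap = snap.transformed(rot, rng.uniform(-1.0, 1.0, size=3))
    snap.true_mode = mode

    fired = modes_mod.classify(snap, criteria)
    if mode == "none":
        if fired:
            raise InconsistentFixtureError(
                f"'none' geometry still fires {sorted(fired)}"
            )
    elif mode not in fired:
        raise InconsistentFixtureError(
            f"requested {mode} geometry (sep={sep} nm, angle={ang} deg) "
            f"does not satisfy the {mode} criteria"
        )
    snap.validate()
    return snap
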