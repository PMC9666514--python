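"""Geometric classification of nucleobase / side-chain interaction modes.

Detects π–π stacking, cation–π, anion–π and hydrogen bonds in annotated
snapshots, and aggregates per-mode occupancy fractions over the snapshot
ensemble of the umbrella window nearest the PMF minimum.

The defining cutoffs are conventional geometric criteria and are fully
config-exposed:

* stacking — ring-centroid distance ≤ 0.45 nm and interplanar angle ≤ 30°
  (angle between best-fit plane normals, folded to [0°, 90°]);
* ion–π — charged-group centroid within 0.50 nm of a ring centroid and
  within 45° of the ring normal;
* hydrogen bond — donor–acceptor distance ≤ 0.35 nm and D–H···A angle ≥ 150°.

All distance/angle boundaries are inclusive. Occupancy reporting follows the
study's wording: π-based modes are "dominant" at occupancy ≥ 50% (inclusive),
hydrogen bonds are reported above 10% (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from basepref.errors import GeometryError
from basepref.snapshot import InteractionSnapshot, ring_plane

PI_MODES = ("stacking", "cation_pi", "anion_pi")


@dataclass(frozen=True)
class GeometricCriteria:
    stacking_max_distance: float = 0.45  # nm, ring centroid to ring centroid
    stacking_max_angle: float = 30.0     # deg, interplanar
    ionpi_max_distance: float = 0.50     # nm, charge centroid to ring centroid
    ionpi_max_angle: float = 45.0        # deg, from ring normal
    hbond_max_da: float = 0.35           # nm, donor to acceptor
    hbond_min_angle: float = 150.0       # deg, D-H...A

    def __post_init__(self):
        for d in (self.stacking_max_distance, self.ionpi_max_distance, self.hbond_max_da):
            if d <= 0:
                raise ValueError("distance cutoffs must be > 0")
        for a in (self.stacking_max_angle, self.ionpi_max_angle, self.hbond_min_angle):
            if not (0.0 <= a <= 180.0):
                raise ValueError("angle cutoffs must lie in [0, 180]")


DEFAULT_CRITERIA = GeometricCriteria()


def _fold_angle(deg: float) -> float:
    """Fold an angle between undirected axes to [0, 90] degrees."""
    deg = deg % 180.0
    return min(deg, 180.0 - deg)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_stacking(s: InteractionSnapshot, c: GeometricCriteria = DEFAULT_CRITERIA) -> bool:
    """True iff any base-ring / side-chain-ring pair is stacked."""
    base_rings = s.rings("base")
    side_rings = s.rings("sidechain")
    if not base_rings or not side_rings:
        raise GeometryError("both partners need at least one annotated ring")
    for rb in base_rings:
        cb, _ = ring_plane(rb)
        for rs in side_rings:
            cs, _ = ring_plane(rs)
            if np.linalg.norm(cb - cs) > c.stacking_max_distance:
                continue
            _, nb = ring_plane(rb)
            _, ns = ring_plane(rs)
            if _fold_angle(_angle_deg(nb, ns)) <= c.stacking_max_angle:
                return True
    return False


def _charge_centroids(s: InteractionSnapshot, mol: str, charge_class: str) -> list[np.ndarray]:
    pts = [np.array(a.xyz) for a in s.atoms if a.mol == mol and a.charge_class == charge_class]
    return [np.mean(pts, axis=0)] if pts else []


def detect_ion_pi(s: InteractionSnapshot, c: GeometricCriteria = DEFAULT_CRITERIA) -> str:
    """``cation_pi``, ``anion_pi`` or ``none``; cation–π wins a tie."""
    hits = set()
    for ring_mol, ion_mol in (("base", "sidechain"), ("sidechain", "base")):
        try:
            rings = s.rings(ring_mol)
        except GeometryError:
            rings = []
        for ring in rings:
            centroid, normal = ring_plane(ring)
            for cls in ("cation", "anion"):
                for q in _charge_centroids(s, ion_mol, cls):
                    vec = q - centroid
                    if np.linalg.norm(vec) > c.ionpi_max_distance:
                        continue
                    if _fold_angle(_angle_deg(vec, normal)) <= c.ionpi_max_angle:
                        hits.add(cls)
    if "cation" in hits:
        return "cation_pi"
    if "anion" in hits:
        return "anion_pi"
    return "none"


def detect_hbonds(
    s: InteractionSnapshot, c: GeometricCriteria = DEFAULT_CRITERIA
) -> list[tuple[int, int, int]]:
    """All intermolecular (donor, H, acceptor) index triples meeting the cutoffs."""
    out = []
    for hi, h in enumerate(s.atoms):
        if not h.is_h:
            continue
        di = h.bonded_to
        if di is None or not s.atoms[di].is_donor:
            raise GeometryError(f"H atom {hi} has no covalent donor assignment")
        d = s.atoms[di]
        hxyz = np.array(h.xyz)
        dxyz = np.array(d.xyz)
        for ai, a in enumerate(s.atoms):
            if not a.is_acceptor or a.mol == d.mol:
                continue
            axyz = np.array(a.xyz)
            if np.linalg.norm(dxyz - axyz) > c.hbond_max_da:
                continue
            if _angle_deg(dxyz - hxyz, axyz - hxyz) >= c.hbond_min_angle:
                out.append((di, hi, ai))
    return out


def fires(mode: str, s: InteractionSnapshot, c: GeometricCriteria = DEFAULT_CRITERIA) -> bool:
    """Whether one named mode is geometrically present in a snapshot."""
    if mode == "stacking":
        try:
            return detect_stacking(s, c)
        except GeometryError:
            return False
    if mode in ("cation_pi", "anion_pi"):
        return detect_ion_pi(s, c) == mode
    if mode == "hbond":
        try:
            return len(detect_hbonds(s, c)) > 0
        except GeometryError:
            return False
    raise ValueError(f"unknown mode {mode!r}")


def classify(s: InteractionSnapshot, c: GeometricCriteria = DEFAULT_CRITERIA) -> set[str]:
    """Set of all modes present (empty set = no detector fires)."""
    return {m for m in ("stacking", "cation_pi", "anion_pi", "hbond") if fires(m, s, c)}


def occupancy(
    snapshots: list[InteractionSnapshot],
    mode: str,
    c: GeometricCriteria = DEFAULT_CRITERIA,
) -> float:
    """Fraction of snapshots in which ``mode`` is present."""
    if not snapshots:
        raise ValueError("occupancy of an empty snapshot list is undefined")
    return sum(fires(mode, s, c) for s in snapshots) / len(snapshots)


def occupancy_table(
    snapshots: list[InteractionSnapshot],
    c: GeometricCriteria = DEFAULT_CRITERIA,
    modes: tuple[str, ...] = ("stacking", "cation_pi", "anion_pi", "hbond"),
) -> pd.DataFrame:
    """Per-mode occupancy rows for one (pair, solvent) snapshot ensemble."""
    if not snapshots:
        raise ValueError("empty snapshot list")
    first = snapshots[0]
    pair = f"{first.base_name}/{first.residue_name}"
    rows = [
        {
            "pair": pair,
            "solvent": first.solvent,
            "mode": m,
            "fraction": occupancy(snapshots, m, c),
            "n": len(snapshots),
        }
        for m in modes
    ]
    return pd.DataFrame(rows)


def dominant_modes(
    table: pd.DataFrame,
    pi_threshold: float = 0.5,
    hbond_threshold: float = 0.1,
) -> pd.DataFrame:
    """Rows meeting the reporting thresholds.

    π-based modes (stacking, cation–π, anion–π) are kept at fraction ≥
    ``pi_threshold`` ("50% of time or more" — inclusive); hydrogen bonds at
    fraction > ``hbond_threshold`` ("more than 10%" — strict).
    """
    if table.empty:
        return table.copy()
    is_pi = table["mode"].isin(PI_MODES)
    keep = (is_pi & (table["fraction"] >= pi_threshold)) | (
        (table["mode"] == "hbond") & (table["fraction"] > hbond_threshold)
    )
    return table[keep].reset_index(drop=True)


def window_at_minimum(centers, r_min: float) -> int:
    """Index of the umbrella window whose bias center is nearest the PMF minimum."""
    centers = np.asarray(centers, dtype=float)
    return int(np.argmin(np.abs(centers - r_min)))
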