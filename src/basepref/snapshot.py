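"""Atomic snapshot of one nucleobase / side-chain pose.

A deliberately format-agnostic carrier: atoms with coordinates (nm) plus the
chemical annotations the interaction classifiers need — ring membership,
formal-charge class, and hydrogen-bond donor/acceptor/H flags. Chemistry
perception is out of scope: the flags are inputs, not inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from basepref.errors import GeometryError

CHARGE_CLASSES = ("cation", "anion", "neutral")


@dataclass
class Atom:
    element: str
    xyz: tuple[float, float, float]
    mol: str  # "base" or "sidechain"
    ring_id: int | None = None
    charge_class: str = "neutral"
    is_donor: bool = False
    is_acceptor: bool = False
    is_h: bool = False
    bonded_to: int | None = None  # index of the covalent donor heavy atom, for H

    def __post_init__(self):
        if self.charge_class not in CHARGE_CLASSES:
            raise ValueError(f"bad charge class {self.charge_class!r}")


@dataclass
class InteractionSnapshot:
    atoms: list[Atom]
    base_name: str = "5mC"
    residue_name: str = "X"
    solvent: str = "water"
    true_mode: str | None = None  # planted label, synthetic fixtures only

    def coords(self, mol: str | None = None) -> np.ndarray:
        idx = self.indices(mol)
        return np.array([self.atoms[i].xyz for i in idx], dtype=float)

    def indices(self, mol: str | None = None) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if mol is None or a.mol == mol]

    def rings(self, mol: str) -> list[np.ndarray]:
        """Coordinate arrays of each annotated ring of one partner."""
        groups: dict[int, list] = {}
        for a in self.atoms:
            if a.mol == mol and a.ring_id is not None:
                groups.setdefault(a.ring_id, []).append(a.xyz)
        rings = [np.array(v, dtype=float) for _, v in sorted(groups.items())]
        for ring in rings:
            if len(ring) < 3:
                raise GeometryError("ring with fewer than 3 atoms")
        return rings

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "InteractionSnapshot":
        """Rigid-body transformed copy (used for invariance checks)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = []
        for a in self.atoms:
            new = Atom(**{**asdict(a), "xyz": tuple(rotation @ np.array(a.xyz) + translation)})
            atoms.append(new)
        return InteractionSnapshot(
            atoms, self.base_name, self.residue_name, self.solvent, self.true_mode
        )

    def validate(self) -> None:
        """Enforce structural invariants: ring size/coplanarity, H bonding."""
        for mol in ("base", "sidechain"):
            for ring in self._raw_rings(mol):
                if len(ring) < 5:
                    raise GeometryError("annotated ring has fewer than 5 atoms")
                if plane_deviation(ring) >= 0.02:
                    raise GeometryError("ring deviates from planarity by >= 0.02 nm")
        for i, a in enumerate(self.atoms):
            if a.is_h:
                j = a.bonded_to
                if j is None or not (0 <= j < len(self.atoms)) or not self.atoms[j].is_donor:
                    raise GeometryError(f"H atom {i} lacks a covalent donor assignment")

    def _raw_rings(self, mol: str) -> list[np.ndarray]:
        groups: dict[int, list] = {}
        for a in self.atoms:
            if a.mol == mol and a.ring_id is not None:
                groups.setdefault(a.ring_id, []).append(a.xyz)
        return [np.array(v, dtype=float) for v in groups.values()]


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane (SVD)."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def plane_deviation(coords: np.ndarray) -> float:
    """Maximum distance of any ring atom from the best-fit plane, nm."""
    centroid, normal = ring_plane(coords)
    return float(np.abs((coords - centroid) @ normal).max())


# --------------------------------------------------------------------------
# JSON round-trip for snapshot files.

def snapshot_to_json(s: InteractionSnapshot) -> str:
    return json.dumps(asdict(s), indent=1)


def snapshot_from_json(text: str) -> InteractionSnapshot:
    raw = json.loads(text)
    atoms = [Atom(**{**a, "xyz": tuple(a["xyz"])}) for a in raw.pop("atoms")]
    return InteractionSnapshot(atoms=atoms, **raw)


def write_snapshots(snapshots: list[InteractionSnapshot], path) -> None:
    Path(path).write_text(
        json.dumps([json.loads(snapshot_to_json(s)) for s in snapshots])
    )


def read_snapshots(path) -> list[InteractionSnapshot]:
    raw = json.loads(Path(path).read_text())
    out = []
    for rec in raw:
        atoms = [Atom(**{**a, "xyz": tuple(a["xyz"])}) for a in rec.pop("atoms")]
        out.append(InteractionSnapshot(atoms=atoms, **rec))
    return out
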