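"""Toy protein/nucleobase complexes in PDB format.

Builds minimal but valid PDB text with a controlled interface composition:
a planar cytosine-like nucleobase (residue ``5CM`` for 5-methylcytosine or
``DC`` for cytosine) on chain B, and single-atom (CA) protein residues on
chain A placed at one of three radii:

* ``interface`` — within van-der-Waals contact of the base (the nearest base
  heavy atom lies inside the default contact cutoff of r_i + r_j + 0.5 Å);
* ``surface``  — ≥ 8 Å from the base on a wide Fibonacci sphere, fully
  solvent-exposed;
* ``buried``   — enclosed in an icosahedral cage of Gly CA atoms so the
  1.4 Å probe cannot reach the central atom (the cage Gly atoms themselves
  contribute ordinary Gly surface area).

Using one CA per residue makes planted area compositions analytically
tractable while still exercising the real parsing/SASA/contact machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from basepref.errors import LayoutError

PLACEMENTS = ("interface", "surface", "buried")

AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Declarative layout of one toy complex."""

    residues: tuple[tuple[str, str], ...]
    base_type: str = "5mC"  # "5mC" -> residue 5CM, "CYT" -> residue DC
    interface_radius: float = 4.9   # Å from base center, in the base plane
    surface_radius: float = 30.0    # Å
    buried_radius: float = 15.0     # Å

    def __post_init__(self):
        if self.base_type not in ("5mC", "CYT"):
            raise ValueError("base_type must be '5mC' or 'CYT'")
        for name, placement in self.residues:
            if name.upper() not in AA3:
                raise ValueError(f"unknown residue name {name!r}")
            if placement not in PLACEMENTS:
                raise ValueError(f"unknown placement {placement!r}")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _icosahedron(radius: float) -> np.ndarray:
    g = (1 + 5**0.5) / 2
    verts = np.array(
        [[-1, g, 0], [1, g, 0], [-1, -g, 0], [1, -g, 0],
         [0, -1, g], [0, 1, g], [0, -1, -g], [0, 1, -g],
         [g, 0, -1], [g, 0, 1], [-g, 0, -1], [-g, 0, 1]],
        dtype=float,
    )
    return radius * verts / np.linalg.norm(verts[0])


def _base_atoms(base_type: str) -> list[tuple[str, str, np.ndarray]]:
    """(atom name, element, xyz Å) of the idealized pyrimidine."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    elements = ["N", "C", "N", "C", "C", "C"]
    ang = np.arange(6) * np.pi / 3.0
    ring = 1.39 * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
    atoms = [(n, e, p) for n, e, p in zip(names, elements, ring)]
    # Exocyclic O2 (on C2), N4 (on C4), radially outward at 2.6 Å.
    for parent, name, elem in ((1, "O2", "O"), (3, "N4", "N")):
        direction = ring[parent] / np.linalg.norm(ring[parent])
        atoms.append((name, elem, 2.6 * direction))
    if base_type == "5mC":
        direction = ring[4] / np.linalg.norm(ring[4])
        atoms.append(("C5M", "C", 2.6 * direction))
    return atoms


def _pdb_line(record, serial, name, resname, chain, resseq, xyz, element, occ=1.0):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field}{'':1}{resname:>3} {chain}"
        f"{resseq:>4}{'':1}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """Render the layout to PDB text; raises LayoutError if unplaceable."""
    groups = {p: [name.upper() for name, q in spec.residues if q == p] for p in PLACEMENTS}
    n_int = len(groups["interface"])
    if n_int > 15:
        raise LayoutError("more than 15 interface residues cannot be placed in contact")

    protein: list[tuple[str, np.ndarray]] = []  # (resname, CA xyz)
    if n_int:
        ang = 2 * np.pi * np.arange(n_int) / n_int + np.pi / 6  # offset from ring atoms
        for name, a in zip(groups["interface"], ang):
            protein.append((name, spec.interface_radius * np.array([np.cos(a), np.sin(a), 0.0])))
    for name, pos in zip(groups["surface"], _fibonacci_sphere(max(len(groups["surface"]), 1), spec.surface_radius)):
        protein.append((name, pos))
    cage_atoms: list[np.ndarray] = []
    for name, pos in zip(groups["buried"], _fibonacci_sphere(max(len(groups["buried"]), 1), spec.buried_radius)):
        protein.append((name, pos))
        cage_atoms.extend(pos + v for v in _icosahedron(3.4))

    base = _base_atoms(spec.base_type)

    # Inter-residue steric check (covalent contacts within the base are fine).
    heavy = np.array([p for _, p in protein] + cage_atoms + [p for _, _, p in base])
    group = np.array(
        list(range(len(protein)))
        + [len(protein) + i for i in range(len(cage_atoms))]
        + [-1] * len(base)
    )
    if len(heavy) > 1:
        d = np.linalg.norm(heavy[:, None, :] - heavy[None, :, :], axis=-1)
        inter = group[:, None] != group[None, :]
        np.fill_diagonal(d, np.inf)
        dmin = d[inter].min()
        if dmin < 2.0:
            raise LayoutError(f"steric overlap: closest heavy-atom pair at {dmin:.2f} Å")

    lines = []
    serial = 1
    resseq = 1
    for name, pos in protein:
        lines.append(_pdb_line("ATOM", serial, "CA", name, "A", resseq, pos, "C"))
        serial += 1
        resseq += 1
    # Gly cage around each buried residue.
    for name, pos in zip(groups["buried"], _fibonacci_sphere(max(len(groups["buried"]), 1), spec.buried_radius)):
        for v in _icosahedron(3.4):
            lines.append(_pdb_line("ATOM", serial, "CA", "GLY", "A", resseq, pos + v, "C"))
            serial += 1
            resseq += 1
    lines.append("TER\n")
    base_resname = "5CM" if spec.base_type == "5mC" else "DC"
    record = "HETATM" if spec.base_type == "5mC" else "ATOM"
    for name, elem, pos in base:
        lines.append(_pdb_line(record, serial, name, base_resname, "B", 1, pos, elem))
        serial += 1
    lines.append("END\n")
    return "".join(lines)
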