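"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from basepref.models import PMFModel
from basepref.synthetic import simulate_series


@pytest.fixture(scope="session")
def gaussian_model() -> PMFModel:
    """The reference well used throughout: ε = 8 kJ/mol, r0 = 0.5 nm, σ = 0.1 nm."""
    return PMFModel("gaussian_well", epsilon=8.0, r0=0.5, sigma=0.1)


@pytest.fixture(scope="session")
def gaussian_series(gaussian_model):
    """Default 16-window series at 10^4 samples/window, seed 1 (shared, read-only)."""
    return simulate_series(gaussian_model, n_per_window=10_000, seed=1)


def mc_sasa(coords, radii, probe: float = 1.4, n_points: int = 200_000, seed: int = 0):
    """Monte-Carlo solvent-accessible surface areas, Å² per atom.

    Independent of the Shrake–Rupley implementation under test: uniform
    random points on each atom's probe-expanded sphere, counting the
    fraction outside every other expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    rng = np.random.default_rng(seed)
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * v
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        areas[i] = free.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas
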