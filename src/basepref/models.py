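"""Parametric potential-of-mean-force models.

These closed-form free-energy curves stand in for the unknown PMF between a
nucleobase and a side-chain analog along their center-of-geometry distance.
They provide exact ground truth for testing the umbrella-sampling → WHAM →
binding-free-energy chain: samples are drawn from the model under a known
bias and the reconstruction must recover the model.

Every family evaluates W*(r) for any r >= 0 (needed for the bound-volume
integral down to r = 0) and decays to 0 on its large-separation plateau.
The ``domain`` is the sampling range only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

FAMILIES = ("flat", "square_well", "gaussian_well", "double_well")


@dataclass(frozen=True)
class PMFModel:
    """A closed-form PMF W*(r).

    Parameters
    ----------
    family
        One of ``flat``, ``square_well``, ``gaussian_well``, ``double_well``.
    epsilon
        Well depth, kJ/mol (ignored for ``flat``).
    r0
        Well center, nm.
    sigma
        Well width, nm. For ``square_well`` this is the full width of the
        flat-bottom region; for the Gaussian families the Gaussian sigma.
    domain
        Sampling domain [r_lo, r_hi], nm.
    r1, epsilon1
        Second well center/depth for ``double_well``.
    """

    family: str
    epsilon: float = 0.0
    r0: float = 0.5
    sigma: float = 0.1
    domain: tuple[float, float] = (0.2, 2.2)
    r1: float | None = None
    epsilon1: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown PMF family {self.family!r}")
        lo, hi = self.domain
        if not (0.0 <= lo < hi and np.isfinite(hi)):
            raise ValueError(f"invalid domain {self.domain}")
        if self.family == "double_well" and self.r1 is None:
            object.__setattr__(self, "r1", self.r0 + 0.4)
        if self.family == "double_well" and self.epsilon1 is None:
            object.__setattr__(self, "epsilon1", 0.5 * self.epsilon)

    def w(self, r: ArrayLike) -> NDArray[np.float64]:
        """Evaluate W*(r) in kJ/mol for r >= 0 (vectorized)."""
        r = np.asarray(r, dtype=float)
        if self.family == "flat":
            return np.zeros_like(r)
        if self.family == "square_well":
            lo = self.r0 - 0.5 * self.sigma
            hi = self.r0 + 0.5 * self.sigma
            return np.where((r >= lo) & (r <= hi), -self.epsilon, 0.0)
        if self.family == "gaussian_well":
            return -self.epsilon * np.exp(-((r - self.r0) ** 2) / (2 * self.sigma**2))
        # double_well
        w = -self.epsilon * np.exp(-((r - self.r0) ** 2) / (2 * self.sigma**2))
        w -= self.epsilon1 * np.exp(-((r - self.r1) ** 2) / (2 * self.sigma**2))
        return w

    def well_edges(self) -> list[float]:
        """Discontinuity locations (for quadrature subdivision)."""
        if self.family == "square_well":
            return [self.r0 - 0.5 * self.sigma, self.r0 + 0.5 * self.sigma]
        return []


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias U_i(r) = 1/2 k (r - center)^2 + offset.

    The additive ``offset`` (kJ/mol) is physically inert — WHAM output must
    be invariant to it — and exists to make that gauge property testable.
    """

    center: float
    force_constant: float
    offset: float = 0.0

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")

    def energy(self, r: ArrayLike) -> NDArray[np.float64]:
        r = np.asarray(r, dtype=float)
        return 0.5 * self.force_constant * (r - self.center) ** 2 + self.offset


@dataclass
class UmbrellaWindow:
    """Distance samples collected under one harmonic bias."""

    bias: BiasSpec
    samples: NDArray[np.float64]
    seed: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("window must contain at least one sample")

    @property
    def sample_count(self) -> int:
        return int(self.samples.size)
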