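"""Umbrella-window generation: equilibrium draws from a biased PMF.

The reaction coordinate is a 3-D center-of-geometry distance, so the
unbiased single-window density carries the spherical volume element:

    p_i(r)  ∝  r^2 · exp(−β [W*(r) + U_i(r)])      on the model domain,

with U_i the harmonic bias. Sampling is by inverse-CDF lookup on a dense
grid — deterministic given a seed and free of rejection-rate pathologies at
stiff biases.

Samples are i.i.d.; real MD output is autocorrelated, which affects error
bars but not expectations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from basepref import constants
from basepref.errors import UnsampleableWindowError
from basepref.models import BiasSpec, PMFModel, UmbrellaWindow

#: Inverse-CDF grid resolution.
GRID_POINTS = 2**14


def subseed(master: int, *indices: int) -> int:
    """Derive an isolated child seed from a master seed and index path.

    Uses numpy's SeedSequence entropy mixing so windows sharing a master
    seed are statistically independent; result fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _biased_logdensity(model: PMFModel, bias: BiasSpec, r: np.ndarray, temperature: float) -> np.ndarray:
    beta = 1.0 / constants.kt(temperature)
    with np.errstate(divide="ignore"):
        logr2 = 2.0 * np.log(r)
    return logr2 - beta * (model.w(r) + bias.energy(r))


def sample_window(
    model: PMFModel,
    bias: BiasSpec,
    n: int,
    seed: int,
    temperature: float = constants.DEFAULT_T,
) -> UmbrellaWindow:
    """Draw ``n`` i.i.d. distances from the biased density of one window.

    Raises
    ------
    UnsampleableWindowError
        If exp(−β(W + U)) underflows to zero on the whole domain (bias
        center far outside the domain with a huge force constant).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = model.domain
    grid = np.linspace(max(lo, 1e-12), hi, GRID_POINTS)
    logp = _biased_logdensity(model, bias, grid, temperature)
    # Literal underflow check before any rescaling: an all-zero raw density
    # means the window cannot be realized, not merely that it is peaked.
    if not np.any(np.exp(logp) > 0.0):
        raise UnsampleableWindowError(
            f"biased density underflows everywhere for center={bias.center} nm, "
            f"k={bias.force_constant} kJ/mol/nm^2"
        )
    pdf = np.exp(logp - logp.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    samples = np.interp(rng.random(n), cdf, grid)
    return UmbrellaWindow(bias=bias, samples=samples, seed=int(seed))


def simulate_series(
    model: PMFModel,
    centers=constants.DEFAULT_CENTERS,
    force_constant: float = constants.DEFAULT_FORCE_CONSTANT,
    n_per_window: int = 10_000,
    seed: int = 0,
    temperature: float = constants.DEFAULT_T,
) -> list[UmbrellaWindow]:
    """One window per bias center (default ladder 0.4–1.9 nm, step 0.1)."""
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    return [
        sample_window(
            model,
            BiasSpec(center=float(c), force_constant=force_constant),
            n_per_window,
            seed=subseed(seed, i),
            temperature=temperature,
        )
        for i, c in enumerate(centers)
    ]


class UmbrellaSeries:
    """A window series that can be extended in place, all windows together.

    Mirrors the study protocol in which unconverged production runs are
    prolonged at every restraining distance simultaneously.
    """

    def __init__(
        self,
        model: PMFModel,
        centers=constants.DEFAULT_CENTERS,
        force_constant: float = constants.DEFAULT_FORCE_CONSTANT,
        n_initial: int = 10_000,
        seed: int = 0,
        temperature: float = constants.DEFAULT_T,
    ):
        self.model = model
        self.centers = np.asarray(centers, dtype=float)
        self.force_constant = force_constant
        self.seed = int(seed)
        self.temperature = temperature
        self._round = 0
        self.windows = simulate_series(
            model, centers, force_constant, n_initial, seed, temperature
        )

    def extend(self, n_additional: int) -> None:
        """Append ``n_additional`` fresh draws to every window."""
        self._round += 1
        for i, w in enumerate(self.windows):
            extra = sample_window(
                self.model,
                w.bias,
                n_additional,
                seed=subseed(self.seed, i, self._round),
                temperature=self.temperature,
            )
            w.samples = np.concatenate([w.samples, extra.samples])


# ---------------------------------------------------------------------------
# Window files: TSV with header comments, plus a JSON series manifest.

def write_window_tsv(window: UmbrellaWindow, path) -> None:
    path = Path(path)
    header = (
        f"#center={window.bias.center:g}\n"
        f"#k={window.bias.force_constant:g}\n"
        f"#seed={window.seed}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, window.samples, fmt="%.9f")


def read_window_tsv(path) -> UmbrellaWindow:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    samples = np.loadtxt(path, comments="#")
    return UmbrellaWindow(
        bias=BiasSpec(center=float(meta["center"]), force_constant=float(meta["k"])),
        samples=np.atleast_1d(samples),
        seed=int(meta.get("seed", 0)),
    )


def write_series(windows: list[UmbrellaWindow], directory) -> Path:
    """Write one TSV per window plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, w in enumerate(windows):
        name = f"window_{i:02d}.tsv"
        write_window_tsv(w, directory / name)
        files.append(name)
    manifest = directory / "series.json"
    manifest.write_text(json.dumps({"windows": files}, indent=2))
    return manifest


def read_series(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    return [read_window_tsv(manifest_path.parent / f) for f in manifest["windows"]]
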