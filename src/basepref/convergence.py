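"""Split-half convergence control and replicate statistics.

The production protocol splits each window's samples into first and second
halves (the proxy for consecutive time segments), runs the full PMF → ΔG
chain on each half, and declares convergence when the two ΔG estimates agree
to within 1.5 kJ/mol. An unconverged series is extended — every window
together — and re-checked on the full accumulated sample set until the
criterion is met or a round budget is exhausted.

Replicate summaries report mean and sample SD (ddof = 1) over independent
repeats, flagging SDs above the 0.58 kJ/mol reporting threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from basepref import constants, pmf
from basepref.errors import BasePrefError
from basepref.models import UmbrellaWindow


@dataclass
class PMFSettings:
    """Settings threaded through the estimation chain by the checker."""

    bin_width: float = constants.DEFAULT_BIN_WIDTH
    temperature: float = constants.DEFAULT_T
    plateau: tuple[float, float] = constants.DEFAULT_PLATEAU
    r_c: float | None = None
    v_standard: float = constants.V_STANDARD


@dataclass
class ConvergenceReport:
    dg_first_half: float
    dg_second_half: float
    difference: float                  # |dg1 - dg2|, kJ/mol
    threshold: float = constants.CONVERGENCE_THRESHOLD
    converged: bool = False
    extensions_performed: int = 0
    dg_full: float | None = None       # ΔG on the full accumulated series
    note: str | None = None            # e.g. why a half-estimate was unusable

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReplicateSummary:
    values: list[float]
    mean: float
    sd: float
    flag_large: bool
    threshold: float = constants.REPLICATE_SD_THRESHOLD

    @property
    def n_replicates(self) -> int:
        return len(self.values)


def _half_windows(windows: list[UmbrellaWindow], which: int) -> list[UmbrellaWindow]:
    out = []
    for w in windows:
        n = w.sample_count
        half = w.samples[: n // 2] if which == 0 else w.samples[n // 2 :]
        out.append(UmbrellaWindow(bias=w.bias, samples=half.copy(), seed=w.seed))
    return out


def split_half_check(
    windows: list[UmbrellaWindow],
    settings: PMFSettings | None = None,
    threshold: float = constants.CONVERGENCE_THRESHOLD,
) -> ConvergenceReport:
    """Run the estimation chain on each sample half and compare ΔG."""
    settings = settings or PMFSettings()
    if any(w.sample_count < 2 for w in windows):
        raise ValueError("every window needs at least 2 samples to split")
    r_c = settings.r_c
    if r_c is None:
        # Fix one bound cutoff from the full series so both halves measure
        # the same bound region; otherwise cutoff jitter between halves
        # masquerades as ΔG drift.
        h = pmf.histogram_windows(windows, bin_width=settings.bin_width,
                                  temperature=settings.temperature)
        p, _, _ = pmf.wham_solve(h)
        full = pmf.pmf_from_density(p, h, plateau=settings.plateau)
        r_c = pmf.default_rc(full)
    dgs = []
    for which, label in ((0, "first"), (1, "second")):
        try:
            fe, _ = pmf.estimate_dg(
                _half_windows(windows, which),
                bin_width=settings.bin_width,
                temperature=settings.temperature,
                plateau=settings.plateau,
                r_c=r_c,
                v_standard=settings.v_standard,
            )
        except Exception as exc:
            raise type(exc)(f"{label} half: {exc}") from exc
        dgs.append(fe.dg)
    diff = abs(dgs[0] - dgs[1])
    return ConvergenceReport(
        dg_first_half=dgs[0], dg_second_half=dgs[1], difference=diff,
        threshold=threshold, converged=diff <= threshold,
    )


def extend_until_converged(
    series,
    increment: int = 2000,
    max_rounds: int = 10,
    settings: PMFSettings | None = None,
    threshold: float = constants.CONVERGENCE_THRESHOLD,
) -> ConvergenceReport:
    """Append-then-check loop mirroring "prolonged for all distances".

    ``series`` must expose ``windows`` (list of UmbrellaWindow) and
    ``extend(n_additional)`` appending fresh samples to every window.
    Stops when converged or after ``max_rounds`` extensions (returning an
    unconverged report, not raising).
    """
    settings = settings or PMFSettings()

    def check() -> ConvergenceReport:
        # A half-series that cannot even be estimated (sparse histograms,
        # unsampled plateau) is by definition not converged: extend.
        try:
            return split_half_check(series.windows, settings, threshold)
        except BasePrefError as exc:
            return ConvergenceReport(
                dg_first_half=float("nan"), dg_second_half=float("nan"),
                difference=float("inf"), threshold=threshold, converged=False,
                note=f"half-series estimation failed: {exc}",
            )
        except ValueError as exc:
            return ConvergenceReport(
                dg_first_half=float("nan"), dg_second_half=float("nan"),
                difference=float("inf"), threshold=threshold, converged=False,
                note=f"half-series estimation failed: {exc}",
            )

    rounds = 0
    report = check()
    while not report.converged and rounds < max_rounds:
        series.extend(increment)
        rounds += 1
        report = check()
    report.extensions_performed = rounds
    try:
        fe, _ = pmf.estimate_dg(
            series.windows, bin_width=settings.bin_width,
            temperature=settings.temperature, plateau=settings.plateau,
            r_c=settings.r_c, v_standard=settings.v_standard,
        )
        report.dg_full = fe.dg
    except (BasePrefError, ValueError) as exc:
        report.note = f"full-series estimation failed: {exc}"
    return report


def replicate_stats(
    values,
    threshold: float = constants.REPLICATE_SD_THRESHOLD,
) -> ReplicateSummary:
    """Mean and unbiased SD over replicate ΔG values."""
    values = [float(v) for v in values]
    if len(values) < 2:
        raise ValueError("need at least 2 replicate values")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1))
    return ReplicateSummary(
        values=values, mean=float(arr.mean()), sd=sd,
        flag_large=sd > threshold, threshold=threshold,
    )
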