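"""Cumulative-sum curves over weighted Doppler spectra and the AbC statistic.

For a spectrum ``S`` on bins ``f_1 < ... < f_N`` the cumulative curve is the
running share of the frequency-weighted power,

    C_n = sum_{i<=n} f_i S(f_i) / sum_i f_i S(f_i),   C_0 = 0,

i.e. the fraction of the perfusion signal localised below each frequency.
The curve is invariant under any rescaling of ``S``, so a purely
proportional amplitude change between two conditions leaves it untouched,
while a redistribution of spectral mass across frequency (a change in the
speed distribution of the scatterers) reshapes it.  The Area between Curves
(AbC) quantifies that reshaping: the area enclosed between two
stage-averaged curves from a starting frequency up to their first
intersection; area past the intersection is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateSpectrumError, EmptyIntervalError, GridMismatchError
from .spectral import PowerSpectrum

__all__ = [
    "CumulativeCurve",
    "AbCResult",
    "DEFAULT_F_START",
    "cumulative_curve",
    "average_curve",
    "area_between_curves",
    "abc_between_stages",
]

#: Default starting frequency for AbC integration, the lower edge of the
#: physiological band.
DEFAULT_F_START = 60.0


@dataclass(frozen=True)
class CumulativeCurve:
    """Normalised running sum of the frequency-weighted spectrum.

    ``C`` is non-decreasing, confined to [0, 1] and ends at 1; an implicit
    zero precedes the first bin.  ``meta`` records the band/interval the
    curve was built from.
    """

    f: np.ndarray
    C: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))
        if len(self.f) != len(self.C):
            raise GridMismatchError("frequency and curve arrays differ in length")

    def __len__(self) -> int:
        return len(self.f)


@dataclass(frozen=True)
class AbCResult:
    """Area between two cumulative curves up to their first intersection.

    ``abc`` is the absolute trapezoidal area (Hz x cumulative fraction)
    between `f_start` and `f_cross`; ``crossed`` records whether an actual
    intersection was found (otherwise integration ran to the grid's upper
    edge).
    """

    abc: float
    f_start: float
    f_cross: float
    crossed: bool


def cumulative_curve(spec: PowerSpectrum) -> CumulativeCurve:
    """Cumulative curve of one spectrum.

    Computed as partial sums of ``f * S(f)`` over the total — identical, in
    the discrete setting, to the per-bin recursion
    ``C_n = C_{n-1} + f_n S(f_n) / sum_i f_i S(f_i)``.
    """
    w = spec.f * spec.S
    total = float(np.sum(w))
    if total <= 0:
        raise DegenerateSpectrumError("frequency-weighted spectrum sums to zero")
    return CumulativeCurve(f=spec.f, C=np.cumsum(w) / total)


def _check_grid(f_a: np.ndarray, f_b: np.ndarray, what: str = "curves") -> None:
    if len(f_a) != len(f_b) or not np.array_equal(f_a, f_b):
        raise GridMismatchError(f"{what} are not on the same frequency grid")


def average_curve(
    spectra: Sequence[PowerSpectrum],
    interval: tuple[float, float] | None = None,
    mode: str = "curve-mean",
) -> CumulativeCurve:
    """Stage-averaged cumulative curve.

    Selects the spectra whose start time falls in the half-open window
    ``[interval[0], interval[1])`` (all spectra if `interval` is None) and
    averages their individual cumulative curves pointwise (``mode =
    "curve-mean"``, the default).  ``mode = "spectrum-mean"`` instead builds
    the curve of the mean spectrum; the two differ whenever spectra vary in
    shape within the window.
    """
    if interval is not None:
        t0, t1 = interval
        selected = [s for s in spectra if t0 <= s.t0 < t1]
        if not selected:
            raise EmptyIntervalError(f"no spectra with t0 in [{t0}, {t1}) s")
    else:
        selected = list(spectra)
        if not selected:
            raise EmptyIntervalError("no spectra supplied")
    f = selected[0].f
    for s in selected[1:]:
        _check_grid(f, s.f, "spectra")
    meta = {"interval": interval, "n_spectra": len(selected), "mode": mode}
    if mode == "spectrum-mean":
        mean_S = np.mean([s.S for s in selected], axis=0)
        curve = cumulative_curve(
            PowerSpectrum(f=f, S=mean_S, idc=selected[0].idc, t0=selected[0].t0)
        )
        return CumulativeCurve(f=f, C=curve.C, meta=meta)
    if mode != "curve-mean":
        raise ValueError(f"unknown averaging mode {mode!r}")
    acc = np.zeros(len(f))
    for s in selected:
        acc += cumulative_curve(s).C
    return CumulativeCurve(f=f, C=acc / len(selected), meta=meta)


def area_between_curves(
    curve_a: CumulativeCurve,
    curve_b: CumulativeCurve,
    f_start: float = DEFAULT_F_START,
    atol: float = 1e-12,
) -> AbCResult:
    """AbC between two cumulative curves with the first-intersection rule.

    The difference ``D(f) = C_a(f) - C_b(f)`` is followed from `f_start`;
    the first frequency where it changes sign — located by linear
    interpolation between the bracketing bins, or at a bin where it touches
    zero exactly — ends the integration, and the area up to that point is
    returned in absolute value.  If the curves never cross, integration runs
    to the upper grid edge and ``crossed`` is False.  Differences with
    ``|D| <= atol`` are treated as zero, so a curve and its floating-point
    rescaled copy give an AbC of exactly 0.
    """
    _check_grid(curve_a.f, curve_b.f)
    f = curve_a.f
    if not f[0] <= f_start <= f[-1]:
        raise GridMismatchError(
            f"f_start = {f_start} Hz lies outside the grid span [{f[0]}, {f[-1]}] Hz"
        )
    sel = f >= f_start
    fs_ = f[sel]
    D = curve_a.C[sel] - curve_b.C[sel]
    D = np.where(np.abs(D) <= atol, 0.0, D)

    nonzero = np.nonzero(D)[0]
    if len(nonzero) == 0:
        return AbCResult(abc=0.0, f_start=f_start, f_cross=f_start, crossed=False)

    j0 = int(nonzero[0])  # curves coincide up to j0; separation starts there
    s0 = np.sign(D[j0])
    f_cross = float(fs_[-1])
    crossed = False
    end = len(D) - 1  # last bin index included in the integral
    frac_area = 0.0  # area of the partial segment ending at the crossing
    for i in range(j0 + 1, len(D)):
        if D[i] == 0.0:
            # cumulative curves meet structurally at the upper edge (both end
            # at 1); a zero-touch there is not a crossing, earlier ones are
            f_cross, crossed, end = float(fs_[i]), i < len(D) - 1, i
            break
        if np.sign(D[i]) != s0:
            span = fs_[i] - fs_[i - 1]
            fc = fs_[i - 1] + D[i - 1] / (D[i - 1] - D[i]) * span
            f_cross, crossed, end = float(fc), True, i - 1
            frac_area = 0.5 * D[i - 1] * (fc - fs_[i - 1])
            break
    area = float(np.trapezoid(D[: end + 1], fs_[: end + 1])) + float(frac_area)
    return AbCResult(abc=abs(area), f_start=f_start, f_cross=f_cross, crossed=crossed)


def abc_between_stages(
    spectra: Sequence[PowerSpectrum],
    stage_a: tuple[float, float],
    stage_b: tuple[float, float],
    f_start: float = DEFAULT_F_START,
    mode: str = "curve-mean",
) -> AbCResult:
    """AbC between the stage-averaged curves of two time windows.

    `stage_a` and `stage_b` are ``(t_start, t_end)`` windows in seconds
    (objects with ``t_start``/``t_end`` attributes, e.g.
    :class:`~ldflow.protocol.Stage`, are accepted too).
    """
    win_a = _as_window(stage_a)
    win_b = _as_window(stage_b)
    curve_a = average_curve(spectra, win_a, mode=mode)
    curve_b = average_curve(spectra, win_b, mode=mode)
    return area_between_curves(curve_a, curve_b, f_start=f_start)


def _as_window(stage) -> tuple[float, float]:
    if hasattr(stage, "t_start") and hasattr(stage, "t_end"):
        return (float(stage.t_start), float(stage.t_end))
    t0, t1 = stage
    return (float(t0), float(t1))
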