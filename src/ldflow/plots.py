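"""Plotting helpers: cumulative-curve pairs with the shaded AbC region."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .cumsum import AbCResult, CumulativeCurve

__all__ = ["plot_curve_pair", "plot_perfusion_series"]


def plot_curve_pair(
    curve_a: CumulativeCurve,
    curve_b: CumulativeCurve,
    result: AbCResult | None = None,
    labels: tuple[str, str] = ("stage 1", "stage 3"),
    ax=None,
    path: str | None = None,
):
    """Two stage-averaged cumulative curves with the area between them shaded
    from the starting frequency to their first intersection."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve_a.f, curve_a.C, label=labels[0])
    ax.plot(curve_b.f, curve_b.C, label=labels[1])
    if result is not None:
        shade = (curve_a.f >= result.f_start) & (curve_a.f <= result.f_cross)
        ax.fill_between(
            curve_a.f[shade], curve_a.C[shade], curve_b.C[shade],
            alpha=0.35, color="purple",
            label=f"AbC = {result.abc:.3g}",
        )
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("cumulative fraction of weighted power")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_perfusion_series(series, ax=None, path: str | None = None):
    """Perfusion trace (PU against time) from a sequence of samples."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = np.array([s.t for s in series])
    pu = np.array([s.pu for s in series])
    ax.plot(t, pu, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("perfusion (arb. units)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
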