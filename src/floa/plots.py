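"""Optional matplotlib figures: the agreement band, the residual ACF,
and the difference-vs-average check."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_band", "plot_acf", "plot_difference_vs_average"]


def plot_band(band, diffs=None, ax=None):
    """Band figure: difference curves in grey, bias and limits on top."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    frames = np.arange(len(band.bias))
    if diffs is not None:
        for curve in diffs.to_matrix():
            ax.plot(frames, curve, color="0.7", lw=0.6, zorder=1)
    ax.plot(frames, band.bias, color="crimson", lw=2, label="bias")
    ax.plot(frames, band.upper, color="steelblue", lw=2, label="upper fLoA")
    ax.plot(frames, band.lower, color="seagreen", lw=2, label="lower fLoA")
    ax.set_xlabel("normalized time (frame)")
    ax.set_ylabel("difference (degrees)")
    ax.legend(frameon=False)
    return ax


def plot_acf(acf_result, ax=None):
    """Stem plot of the averaged residual ACF with ±2/sqrt(N) bounds."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    lags, vals = acf_result["lags"], acf_result["acf"]
    ax.vlines(lags, 0, vals, color="k", lw=1.5)
    b = acf_result["bound"]
    ax.axhline(b, ls="--", color="steelblue")
    ax.axhline(-b, ls="--", color="steelblue")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (frames)")
    ax.set_ylabel("autocorrelation")
    return ax


def plot_difference_vs_average(rva_result, ax=None):
    """Scatter of residuals (or differences) against averages."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(rva_result["average"], rva_result["residual"], ".",
            ms=2, alpha=0.4, color="k")
    ax.axhline(0, color="crimson", lw=1)
    ax.set_xlabel("average of the two methods (degrees)")
    ax.set_ylabel("residual (degrees)")
    return ax
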