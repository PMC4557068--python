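"""Minimal plotting helpers for composite curves and driver series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_composite(series, ax=None, color="0.2", band_color="0.8", label=None):
    """Plot a composite curve with its confidence band; age axis reversed
    (past on the left, present on the right)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(series.bin_age, series.ci_low, series.ci_high, color=band_color,
                    label=f"{int(series.ci_level * 100)}% CI")
    ax.plot(series.bin_age, series.mean, color=color, label=label)
    ax.set_xlabel("Age (cal. yr BP)")
    ax.invert_xaxis()
    return ax


def plot_pls(x, y, fitted, ax=None, xlabel="forcing", ylabel="biomass burning"):
    """Scatter of the centred panel with the one-component PLS fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=18, color="0.3")
    order = sorted(range(len(x)), key=lambda i: x[i])
    ax.plot([x[i] for i in order], [fitted[i] for i in order], color="firebrick")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
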