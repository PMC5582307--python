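"""Diagnostic plots: Bland-Altman agreement and window-selection surfaces."""

from __future__ import annotations

import numpy as np

from .kurtosis import SelectionResult
from .metrics import bland_altman


def plot_bland_altman(true_vals, est_vals, ax=None, label: str = ""):
    """Bland-Altman scatter with mean difference and ±2 SD limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    true_vals = np.asarray(true_vals, dtype=float)
    est_vals = np.asarray(est_vals, dtype=float)
    mean_d, lo, hi = bland_altman(true_vals, est_vals)
    ax.plot((true_vals + est_vals) / 2.0, true_vals - est_vals, "k*")
    for y, style in ((mean_d, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="0.4", linestyle=style)
        ax.annotate(f"{y:.1f}", xy=(1.0, y), xycoords=("axes fraction", "data"),
                    fontsize="x-small", ha="left")
    ax.set_xlabel(f"mean of true and estimated {label}".strip())
    ax.set_ylabel("true − estimated")
    return ax


def plot_selection_surfaces(selection: SelectionResult, axes=None):
    """|mismatch| and beat-location-spread surfaces over (IMF, window)."""
    import matplotlib.pyplot as plt

    if selection.mode != "calibrated" or selection.mismatch_surface is None:
        raise ValueError("surfaces exist only for calibrated selections")
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, surface, title in (
        (axes[0], selection.mismatch_surface, "|mismatch error| (%)"),
        (axes[1], selection.varbloc_surface, "beat-location spread (ms)"),
    ):
        im = ax.imshow(surface.to_numpy(), aspect="auto", origin="lower",
                       extent=(surface.columns.min(), surface.columns.max(),
                               surface.index.min(), surface.index.max()))
        ax.set_xlabel("window size (ms)")
        ax.set_ylabel("IMF level")
        ax.set_title(title, fontsize="small")
        plt.colorbar(im, ax=ax)
    return axes
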