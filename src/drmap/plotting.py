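"""Dose-response map figures: mean surface dose with significance contours.

Axis edge labels come from the anatomical convention table in
:mod:`drmap.conventions` (L/R/S/I for bladder maps, P/A for rectum maps).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .conventions import MAP_AXES

__all__ = ["plot_drm"]


def plot_drm(mean_dose: np.ndarray, sig_mask: np.ndarray, organ: str = "bladder",
             path=None, title: str | None = None):
    """Mean-dose map with the significant subregion outlined as a contour."""
    axes_meta = MAP_AXES[organ]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(mean_dose, cmap="inferno", origin="upper", aspect="auto")
    fig.colorbar(im, ax=ax, label="mean dose (Gy)")
    mask = np.asarray(sig_mask, dtype=float)
    if mask.any():
        ax.contour(mask, levels=[0.5], colors="cyan", linewidths=1.5)
    n_rows, n_cols = mean_dose.shape
    ax.text(-0.06, 0.98, axes_meta["top"], transform=ax.transAxes, va="top")
    ax.text(-0.06, 0.02, axes_meta["bottom"], transform=ax.transAxes, va="bottom")
    ax.text(0.0, -0.08, axes_meta["left"], transform=ax.transAxes, ha="left")
    ax.text(0.5, -0.08, axes_meta["center_col_label"], transform=ax.transAxes,
            ha="center")
    ax.text(1.0, -0.08, axes_meta["right"], transform=ax.transAxes, ha="right")
    ax.set_xlabel(axes_meta["cols"], labelpad=18, fontsize=8)
    ax.set_ylabel(axes_meta["rows"], fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
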