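"""Figure export: event scatters, transfer-function overlays, parameter maps.

Figures are built on :class:`matplotlib.figure.Figure` directly (no pyplot
state), so plotting works headless and never touches a GUI backend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

__all__ = [
    "plot_events_scatter",
    "plot_transfer_fits",
    "plot_grid_curves",
    "plot_params_vs_expression",
]


def plot_events_scatter(events: pd.DataFrame, title: str | None = None) -> Figure:
    """Reference vs reporter intensity scatter on log-log axes."""
    fig = Figure(figsize=(5, 4))
    ax = fig.subplots()
    ax.scatter(
        events["ref_intensity"], events["rep_intensity"], s=2, alpha=0.2, linewidths=0
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("reference intensity (a.u.)")
    ax.set_ylabel("reporter intensity (a.u.)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_transfer_fits(items) -> Figure:
    """Overlay transfer functions with their fitted curves.

    ``items`` is an iterable of ``(label, TransferFunction, TransferFitResults
    or None)`` tuples.
    """
    fig = Figure(figsize=(6, 4.5))
    ax = fig.subplots()
    for label, tf, fit in items:
        pts = ax.plot(tf.bin_center, tf.mean_log_rep, "o", ms=3, label=label)
        if fit is not None:
            xs = np.linspace(tf.bin_center[0], tf.bin_center[-1], 200)
            ax.plot(xs, fit.predict(xs), "-", color=pts[0].get_color(), lw=1.2)
    ax.set_xlabel("log10 relative reference intensity")
    ax.set_ylabel("mean log10 relative reporter intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_grid_curves(grid: pd.DataFrame) -> Figure:
    """One overlay figure with every labeled curve of a parameter-grid simulation."""
    fig = Figure(figsize=(6, 4.5))
    ax = fig.subplots()
    for curve_id, curve in grid.groupby("curve_id", sort=False):
        ax.plot(curve["r0"], curve["r"], label=curve_id, lw=1.2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("r0 (unrepressed level)")
    ax.set_ylabel("r (free mRNA)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_params_vs_expression(fit_table: pd.DataFrame) -> Figure:
    """theta and 1/lambda against per-sample expression, colored by category."""
    fig = Figure(figsize=(8, 4))
    axes = fig.subplots(1, 2)
    colors = {"low": "tab:gray", "mid": "tab:red", "high": "tab:blue"}
    for _, row in fit_table.iterrows():
        color = colors.get(row.get("category"), "k")
        x = row.get("expression", np.nan)
        axes[0].scatter(x, row["theta_hat"], color=color)
        axes[1].scatter(x, 1.0 / max(row["lam_hat"], 1e-12), color=color)
    axes[0].set_xlabel("expression (normalized counts)")
    axes[0].set_ylabel(r"$\hat\theta$")
    axes[1].set_xlabel("expression (normalized counts)")
    axes[1].set_ylabel(r"$1/\hat\lambda$")
    for ax in axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    fig.tight_layout()
    return fig
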