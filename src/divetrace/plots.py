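"""Diagnostic figures: standardized cluster profiles and concatenated
transition-point ascents colored by temperature."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_cluster_profiles(X, model, path) -> None:
    """Standardized profiles per cluster with the mean curve overlaid."""
    grid = np.linspace(0, 1, X.shape[1])
    fig, axes = plt.subplots(1, model.k, figsize=(3.2 * model.k, 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for c, ax in enumerate(axes):
        members = X[model.assignments == c]
        for row in members:
            ax.plot(grid, row, color="steelblue", alpha=0.15, lw=0.8)
        ax.plot(grid, model.centroids[c], color="gray", lw=3)
        ax.set_title(f"{model.kind} {c + 1} (n={len(members)})")
        ax.set_xlabel("standardized time")
        ax.invert_yaxis()
    axes[0].set_ylabel("standardized depth")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_concatenated_ascents(ascents, fits, path) -> None:
    """Ascents ordered by apex depth, colored by temperature, with the
    estimated change point marked and its 95% CI as vertical lines."""
    order = np.argsort([-a.depth.max() for a in ascents])
    fig, ax = plt.subplots(figsize=(10, 4))
    offset = 0.0
    for i in order:
        a, f = ascents[i], fits[i]
        t = a.t_s + offset
        if a.temperature is not None:
            ax.scatter(t, a.depth, c=a.temperature, cmap="viridis", s=4,
                       vmin=5, vmax=28)
        else:
            ax.plot(t, a.depth, lw=0.8)
        cp = f.changepoint_s + offset
        cp_depth = f.intercept + f.slope1 * f.changepoint_s
        ax.plot([cp], [cp_depth], "rx", ms=6)
        ax.vlines([f.ci95[0] + offset, f.ci95[1] + offset],
                  a.depth.min(), a.depth.max(), color="gray", lw=0.5, alpha=0.5)
        offset = t[-1] + 600
    ax.invert_yaxis()
    ax.set_xlabel("concatenated time (s)")
    ax.set_ylabel("depth (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
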