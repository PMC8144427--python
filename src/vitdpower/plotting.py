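"""Power-surface visualisation."""

from __future__ import annotations


import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .power import PowerGrid

__all__ = ["plot_power_surface"]


def plot_power_surface(grid: PowerGrid, path=None, cmap: str = "viridis"):
    """Heatmaps of replicate-averaged power against sample size and baseline.

    One panel per (dose, u) combination.  Requires at least a 2 x 2 grid of
    (n, baseline) points.
    """
    avg = grid.averaged()
    if avg["n"].nunique() < 2 or avg["mu"].nunique() < 2:
        raise ValueError("power surface needs >= 2 sample sizes and >= 2 baselines")
    panels = sorted(set(zip(avg["dose"], avg["u"])))
    fig, axes = plt.subplots(
        1, len(panels), figsize=(4.5 * len(panels), 4.0), squeeze=False
    )
    for ax, (dose, u) in zip(axes[0], panels):
        sub = avg[(avg["dose"] == dose) & (avg["u"] == u)]
        table = sub.pivot_table(index="n", columns="mu", values="power")
        im = ax.imshow(
            table.to_numpy(), origin="lower", aspect="auto", cmap=cmap, vmin=0, vmax=1,
            extent=None,
        )
        ax.set_xticks(np.arange(table.shape[1]), [f"{m:g}" for m in table.columns])
        ax.set_yticks(np.arange(table.shape[0]), [f"{n:g}" for n in table.index])
        ax.set_xlabel("baseline 25OHD (nmol/L)")
        ax.set_ylabel("n per arm")
        ax.set_title(f"dose {dose:g} nmol/L, u = {u:g}")
        fig.colorbar(im, ax=ax, label="power")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
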