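"""Diagnostic plots: hexagon loci and eigenshape score space.

Quick-look figures only; publication styling is out of scope.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_hexagon_loci(loci, path, achromatic_radius: float = 0.05):
    """Scatter of colour loci inside the unit hexagon, coloured by sector."""
    fig, ax = plt.subplots(figsize=(6, 6))
    # hexagon outline: vertices every 60 degrees starting at the blue vertex
    th = np.deg2rad(np.arange(0, 361, 60))
    ax.plot(np.sin(th), np.cos(th), color="0.6", lw=1)
    circ = np.linspace(0, 2 * np.pi, 100)
    ax.plot(achromatic_radius * np.cos(circ), achromatic_radius * np.sin(circ),
            color="0.8", lw=0.8, ls="--")
    for sector, sub in loci.groupby("sector"):
        ax.scatter(sub["x"], sub["y"], label=sector, s=25)
    ax.set_xlabel("x (hexagon units)")
    ax.set_ylabel("y (hexagon units)")
    ax.set_aspect("equal")
    ax.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_space(scores, path, axes=(0, 1)):
    """Scatter of specimens on two eigenshape axes, coloured by group."""
    i, j = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in scores.groupby("group"):
        ax.scatter(sub[f"axis_{i + 1}"], sub[f"axis_{j + 1}"], label=group, s=25)
    ax.set_xlabel(f"eigenshape axis {i + 1}")
    ax.set_ylabel(f"eigenshape axis {j + 1}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
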