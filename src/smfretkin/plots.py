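"""Matplotlib renderings of the standard summary figures."""

from __future__ import annotations

import numpy as np

from .kinetics import TDP, TODP
from .thermo import EnergyLandscape


def plot_tdp(tdp: TDP | TODP, ax=None, cmap: str = "viridis", title: str = ""):
    """Heat map of a transition (occupancy) density plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(tdp.edges, tdp.edges, tdp.matrix.T, cmap=cmap, shading="flat")
    ax.plot([0, 1], [0, 1], color="w", lw=0.5, alpha=0.6)
    ax.set_xlabel("E before transition")
    ax.set_ylabel("E after transition")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    return ax


def plot_landscape(ls: EnergyLandscape, ax=None, n_interp: int = 60):
    """Schematic well/barrier profile along the reaction coordinate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    xs, ys = [], []
    for i, s in enumerate(ls.states):
        xs.append(2 * i)
        ys.append(ls.wells[s])
        if i + 1 < len(ls.states):
            nxt = ls.states[i + 1]
            xs.append(2 * i + 1)
            ys.append(ls.wells[s] + ls.barriers[(s, nxt)])
    xs, ys = np.array(xs, float), np.array(ys, float)
    # smooth cosine arcs between the sampled extrema
    fine_x, fine_y = [], []
    for a in range(len(xs) - 1):
        t = np.linspace(0, 1, n_interp)
        fine_x.append(xs[a] + t * (xs[a + 1] - xs[a]))
        fine_y.append(ys[a] + (ys[a + 1] - ys[a]) * (1 - np.cos(np.pi * t)) / 2)
    ax.plot(np.concatenate(fine_x), np.concatenate(fine_y), lw=2)
    for i, s in enumerate(ls.states):
        ax.annotate(s, (2 * i, ls.wells[s]), textcoords="offset points",
                    xytext=(0, -12), ha="center")
    ax.set_xticks([])
    ax.set_ylabel("free energy (J/mol)")
    if ls.condition:
        ax.set_title(ls.condition)
    return ax
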