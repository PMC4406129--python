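"""Optional plotting: the fitted selection surface.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
package stays matplotlib-free.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .selection import SelectionGradients

__all__ = ["plot_selection_surface"]


def plot_selection_surface(gradients: SelectionGradients, z, zbar, path=None, grid=60):
    """Probability of territory acquisition over (own trait, associate trait).

    Draws the logistic surface implied by the fitted gradients with the
    observed (z, zbar) points overlaid. Returns the matplotlib figure;
    saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    z = np.asarray(z, dtype=float)
    zbar = np.asarray(zbar, dtype=float)
    gz = np.linspace(np.nanmin(z), np.nanmax(z), grid)
    gzb = np.linspace(np.nanmin(zbar), np.nanmax(zbar), grid)
    ZZ, BB = np.meshgrid(gz, gzb)
    P = expit(gradients.alpha + gradients.beta_N * ZZ + gradients.beta_S * BB)

    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(ZZ, BB, P, levels=12, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="P(territory acquired)")
    ax.scatter(z, zbar, s=6, c="white", alpha=0.4, linewidths=0)
    ax.set_xlabel("arrival time (sd units)")
    ax.set_ylabel("weighted mean associate arrival time (sd units)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
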