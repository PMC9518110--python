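"""Quick-look plots for fitted surfaces (convenience, not cartography)."""

from __future__ import annotations

import numpy as np


def trellis_heatmap(surface, value: str = "rr_mean", ax=None, cmap: str = "viridis"):
    """Region-by-time heatmap of one column of a long-format surface table.

    A fast visual stand-in for choropleth maps when no boundary geometry is
    available: rows are regions, columns are periods.
    """
    import matplotlib.pyplot as plt

    pivot = surface.pivot(index="region", columns="time", values=value)
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * pivot.shape[1], 1 + 0.35 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(np.arange(pivot.shape[1]), labels=[str(c) for c in pivot.columns])
    ax.set_yticks(np.arange(pivot.shape[0]), labels=[str(r) for r in pivot.index])
    ax.set_xlabel("period")
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax
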