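"""Basic map of the ensemble occurrence surface."""

from __future__ import annotations

import numpy as np


def plot_surface(grid, probability, ax=None, cmap="viridis"):
    """Plot the gridded occurrence probability (NaN cells transparent).

    Returns the matplotlib Axes; sanctuary-zone cells are hatched.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x0, y0 = grid.origin
    cs = grid.cell_size_m
    extent = (x0, x0 + grid.n_cols * cs, y0, y0 + grid.n_rows * cs)
    im = ax.imshow(
        np.asarray(probability, dtype=float),
        origin="lower",
        extent=extent,
        cmap=cmap,
        vmin=0.0,
        vmax=1.0,
    )
    sz = np.where(grid.zone_label == "SZ", 1.0, np.nan)
    ax.contour((grid.zone_label == "SZ").astype(float), levels=[0.5],
               extent=extent, origin="lower", colors="white", linewidths=0.8)
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    ax.figure.colorbar(im, ax=ax, label="occurrence probability")
    return ax
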