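"""Rendering hooks: significance-coloured patterns, map grids and the
cluster heatmap.

These mirror the field's standard displays: mediolateral Z patterns drawn
red where significant and black where silent, and the group-by-group
correlation matrix with cluster outlines and zebrin-band annotations.
"""

from __future__ import annotations

import numpy as np

from .geometry import Z_THRESHOLD, BandCoordinateFrame
from .mapping import MediolateralPattern
from .population import ClusterAssignment, CorrelationMatrix


def plot_pattern(pattern: MediolateralPattern, threshold: float = Z_THRESHOLD, ax=None):
    """Plot a mediolateral pattern, red above threshold, black below."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    x, y = pattern.positions_um, pattern.values
    ax.fill_between(x, 0, y, where=y <= threshold, color="black", step=None)
    ax.fill_between(x, 0, y, where=y > threshold, color="crimson")
    ax.axhline(threshold, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("distance to midline (µm)")
    ax.set_ylabel("Z-score")
    if pattern.soma_position_um is not None:
        ax.axvline(pattern.soma_position_um, color="steelblue", lw=0.8)
    return ax


def plot_correlation_matrix(
    matrix: CorrelationMatrix,
    assignment: ClusterAssignment | None = None,
    frame: BandCoordinateFrame | None = None,
    ax=None,
):
    """Heatmap of the group correlation matrix with cluster outlines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    c = matrix.centers_um
    extent = (c[0], c[-1], c[-1], c[0])
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r", extent=extent)
    plt.colorbar(im, ax=ax, label="Pearson r")
    if assignment is not None:
        for k in np.unique(assignment.labels):
            idx = np.flatnonzero(assignment.labels == k)
            lo, hi = c[idx[0]], c[idx[-1]]
            ax.plot(
                [lo, hi, hi, lo, lo],
                [lo, lo, hi, hi, lo],
                color="navy",
                ls="--",
                lw=1.2,
            )
    if frame is not None:
        for b in frame.boundaries_um[1:-1]:
            if c[0] <= b <= c[-1]:
                ax.axvline(b, color="green", lw=0.8, alpha=0.6)
    ax.set_xlabel("group centre (µm from midline)")
    ax.set_ylabel("group centre (µm from midline)")
    return ax


def plot_map(cmap, threshold: float = Z_THRESHOLD, ax=None):
    """Grid rendering of a connectivity map: square size ~ Z, red if significant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2))
    df = cmap.to_frame()
    zmax = max(df["z"].max(), threshold)
    for _, row in df.iterrows():
        size = 30 + 120 * max(row["z"], 0) / zmax
        color = "crimson" if row["z"] > threshold else "black"
        ax.scatter(row["ml_um"], row["depth_row"], s=size, marker="s", color=color)
    ax.set_xlabel("distance to midline (µm)")
    ax.set_ylabel("depth row")
    ax.invert_yaxis()
    return ax
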