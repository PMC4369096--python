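"""Matplotlib rendering of biplot layouts: filled classification regions
behind sample glyphs, calibrated variable axes with tick markers, 1:1 aspect.

SVG output is made byte-reproducible by fixing the hash salt and stripping
the creation date, so identical layouts render to identical files.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap, to_rgba

from .biplot import BiplotLayout, build_region_grid

__all__ = ["render_biplot"]

_GROUP_COLORS = plt.get_cmap("tab10").colors


def render_biplot(
    layout: BiplotLayout,
    groups,
    path=None,
    resolution: int = 400,
    margin: float = 0.1,
    title: str | None = None,
    point_sizes=None,
    figsize=(7.0, 7.0),
):
    """Render a layout to SVG/PNG (by file suffix) or return the figure.

    ``groups`` holds per-sample class indices for glyph colouring;
    ``point_sizes`` optionally scales glyph area (e.g. pattern multiplicity
    for collapsed binary data).  The classification-region grid is computed
    if the layout does not already carry one.
    """
    groups = np.asarray(groups, dtype=int)
    grid = layout.region_grid
    if grid is None or len(grid.x) != resolution:
        grid = build_region_grid(layout, resolution=resolution, margin=margin)

    J = len(layout.class_labels) if layout.class_labels else int(groups.max()) + 1
    region_cmap = ListedColormap(
        [to_rgba(_GROUP_COLORS[j % 10], alpha=0.18) for j in range(J)]
    )

    fig, ax = plt.subplots(figsize=figsize)
    ax.pcolormesh(
        grid.x,
        grid.y,
        grid.labels,
        cmap=region_cmap,
        vmin=-0.5,
        vmax=J - 0.5,
        shading="nearest",
        rasterized=False,
        zorder=0,
    )
    markers = "osD^vP*"
    for j in range(J):
        sel = groups == j
        label = str(layout.class_labels[j]) if layout.class_labels else f"class {j}"
        sizes = 30.0 if point_sizes is None else 12.0 * np.asarray(point_sizes)[sel]
        ax.scatter(
            layout.scores[sel, 0],
            layout.scores[sel, 1],
            s=sizes,
            marker=markers[j % len(markers)],
            color=_GROUP_COLORS[j % 10],
            edgecolor="black",
            linewidth=0.4,
            label=label,
            zorder=3,
        )

    for axis in layout.axes:
        if not axis.markers:
            continue
        pos = np.array([p for _, p in axis.markers])
        lo, hi = pos[0], pos[-1]
        ax.plot([lo[0], hi[0]], [lo[1], hi[1]], color="grey", lw=0.9, zorder=2)
        for v, p in axis.markers:
            ax.plot(p[0], p[1], marker="|", color="grey", ms=5, zorder=2)
            ax.annotate(
                f"{v:g}", p, textcoords="offset points", xytext=(2, 2),
                fontsize=6, color="grey", zorder=2,
            )
        ax.annotate(
            axis.variable_name, hi, textcoords="offset points", xytext=(4, 4),
            fontsize=8, color="dimgrey", zorder=2,
        )

    ax.set_aspect(layout.aspect)
    ax.set_xlim(grid.x[0], grid.x[-1])
    ax.set_ylim(grid.y[0], grid.y[-1])
    if layout.layout_kind == "two_group":
        ax.set_xlabel("phi_1^2" + (" / s_1" if layout.phi_scale[0] != 1 else ""))
        ax.set_ylabel("phi_2^2" + (" / s_2" if layout.phi_scale[1] != 1 else ""))
    elif layout.layout_kind == "cva":
        ax.set_xlabel("canonical variate 1")
        ax.set_ylabel("canonical variate 2")
    else:
        ax.set_xlabel("PC1 of standardized quadratic scores")
        ax.set_ylabel("PC2 of standardized quadratic scores")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)

    if path is None:
        return fig
    with plt.rc_context({"svg.hashsalt": "qdabiplot"}):
        fig.savefig(path, metadata=_reproducible_metadata(str(path)))
    plt.close(fig)
    return None


def _reproducible_metadata(path: str):
    if path.endswith(".svg"):
        return {"Date": None}
    return None
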