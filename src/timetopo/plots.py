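"""Figure helpers: graph overlays, volcano plots, Kaplan-Meier curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .graphstats import TUMOR, IMMUNE, build_distance_graph

CLASS_COLORS = {TUMOR: "#d4559b", IMMUNE: "#4daf4a", "other": "#bbbbbb"}


def graph_overlay(cells: pd.DataFrame, threshold_px: float = 30.0, ax=None):
    """Cells colored by class with distance-band edges drawn underneath."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    g = build_distance_graph(cells, threshold_px)
    pos = {r.cell_id: (r.x_px, r.y_px) for r in cells.itertuples()}
    for a, b in g.edges():
        (x0, y0), (x1, y1) = pos[a], pos[b]
        ax.plot([x0, x1], [y0, y1], color="0.8", lw=0.5, zorder=1)
    for cls_name, sub in cells.groupby("cls"):
        ax.scatter(sub["x_px"], sub["y_px"], s=8, zorder=2,
                   color=CLASS_COLORS.get(cls_name, "k"), label=cls_name)
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"distance band {threshold_px:g} px")
    return ax


def volcano(results: pd.DataFrame, alpha: float = 0.05, ax=None):
    """-log10 p against LMM coefficient with a reference line at p = alpha."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    conv = results[results["converged"]]
    ax.scatter(conv["coefficient"], -np.log10(conv["p_value"]), s=14, color="0.3")
    ax.axhline(-np.log10(alpha), color="red", ls=":", lw=1)
    sig = conv[conv["p_value"] < alpha]
    for row in sig.itertuples():
        ax.annotate(row.marker, (row.coefficient, -np.log10(row.p_value)),
                    fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("LMM coefficient (log scale)")
    ax.set_ylabel("-log10 p")
    return ax


def km_plot(km_result: dict, ax=None):
    """Kaplan-Meier curves per group with the log-rank p in the title."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for kmf in km_result["fits"].values():
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {km_result['p_value']:.3g}")
    return ax
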