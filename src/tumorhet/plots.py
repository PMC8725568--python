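"""Heatmap and forest-plot rendering for screen results.

The plotted numbers are always exported alongside the figures as TSV; the
TSV, not the pixels, is the reproducible contract.
"""

from __future__ import annotations

import pathlib

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import cluster_zmatrix


def plot_z_heatmap(z: pd.DataFrame, path, linkage: str = "complete",
                   title: str = "Case-case z statistics"):
    """Clustered heatmap: ordering from |z|, colors from signed z.

    Returns the clustered (reordered) DataFrame that was drawn; it is also
    written next to the figure as ``<path>.tsv``.
    """
    row_order, col_order, _, _ = cluster_zmatrix(z, linkage=linkage)
    zc = z.iloc[row_order, :].iloc[:, col_order]
    vmax = max(np.abs(zc.values).max(), 1.0)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * zc.shape[1] + 3), max(3, 0.25 * zc.shape[0] + 2)))
    im = ax.imshow(zc.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(zc.shape[1]), zc.columns, rotation=45, ha="right")
    ax.set_yticks(range(zc.shape[0]), zc.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="z")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    zc.to_csv(str(path) + ".tsv", sep="\t")
    return zc


def plot_forest(or_table: pd.DataFrame, path, variant_id=None,
                title: str | None = None):
    """Forest plot of ORs with 95% CIs on a log x-axis, reference at 1."""
    tab = or_table
    if variant_id is not None:
        tab = tab[tab["variant_id"] == variant_id]
    if tab.empty:
        raise ValueError("empty OR table")
    tab = tab.reset_index() if "category" not in tab.columns else tab
    y = np.arange(len(tab))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(tab) + 1.5))
    ax.errorbar(tab["OR"], y,
                xerr=[tab["OR"] - tab["ci_lo"], tab["ci_hi"] - tab["OR"]],
                fmt="s", color="k", capsize=3)
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(y, tab["category"])
    ax.set_xlabel("odds ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_reports(screen_result, outdir):
    """Write heatmaps (models 2/3) and per-variant forest plots."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if screen_result.z_markers.shape[0] >= 2:
        plot_z_heatmap(screen_result.z_markers, out / "heatmap_markers.svg",
                       title="Marker-specific heterogeneity z")
        written.append(out / "heatmap_markers.svg")
    if screen_result.z_subtypes.shape[0] >= 2:
        plot_z_heatmap(screen_result.z_subtypes, out / "heatmap_subtypes.svg",
                       title="Subtype case-control z")
        written.append(out / "heatmap_subtypes.svg")
    m3 = screen_result.subtype_ors
    for vid in m3["variant_id"].unique():
        p = out / f"forest_{vid}.svg"
        plot_forest(m3[m3["model"] == "model3"], p, variant_id=vid, title=str(vid))
        written.append(p)
    return written
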