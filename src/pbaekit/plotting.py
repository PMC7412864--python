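"""Static plot helpers: scree curve, loading map, dendrogram, GAG curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

__all__ = ["plot_scree", "plot_loading_map", "plot_dendrogram", "plot_gag_summary"]


def plot_scree(scree, selection=None, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(scree.h, scree.rmse, "o-", color="tab:blue")
    if selection is not None:
        ax.axvline(selection.h_selected, color="tab:red", ls="--",
                   label=f"selected h={selection.h_selected}")
        ax.legend()
    ax.set_xlabel("number of PLS components")
    ax.set_ylabel("RMSE of prediction (standardized)")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_loading_map(loadings, path=None):
    fig, ax = plt.subplots(figsize=(6, 6))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=1)
    for _, row in loadings.iterrows():
        color = "tab:green" if row["kind"] == "descriptor" else "tab:blue"
        ax.annotate(row["name"], (row["comp1"], row["comp2"]),
                    color=color, fontsize=7, ha="center")
        ax.plot([0, row["comp1"]], [0, row["comp2"]], color=color, alpha=0.3, lw=0.7)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.axhline(0, color="0.9", lw=0.5)
    ax.axvline(0, color="0.9", lw=0.5)
    ax.set_xlabel("component 1 correlation")
    ax.set_ylabel("component 2 correlation")
    ax.set_aspect("equal")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_dendrogram(tree, path=None):
    fig, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(
        tree.linkage_matrix, labels=[str(i) for i in tree.ids], ax=ax,
        leaf_font_size=7,
    )
    ax.set_ylabel("complete-linkage merge height")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_gag_summary(summary, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, g in summary.groupby("group"):
        ax.errorbar(
            g["day"], g["mean_pct"],
            yerr=[g["mean_pct"] - g["ci_low"], g["ci_high"] - g["mean_pct"]],
            marker="o", capsize=3, label=group,
        )
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative GAG variation (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
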