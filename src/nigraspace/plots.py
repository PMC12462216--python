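"""Optional figure export: volcano plot per contrast and the propagation
dot plot (stationary probability vs betweenness, colored by log2FC sign)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano(de: pd.DataFrame, alpha: float = 0.05, ax=None):
    """Volcano plot of a DE table: log2FC vs -log10 adjusted p."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.clip(de["padj"], 1e-300, None))
    colors = np.where(
        de["direction"] == "up", "firebrick", np.where(de["direction"] == "down", "steelblue", "0.7")
    )
    ax.scatter(de["log2FC"], y, s=6, c=colors, linewidths=0)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    return ax


def netprop_dotplot(result: pd.DataFrame, ax=None):
    """Propagation dot plot: probability vs betweenness, key genes labeled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    degs = result[result["is_deg"]]
    colors = np.where(degs["log2FC"] >= 0, "firebrick", "steelblue")
    ax.scatter(degs["probability"], degs["betweenness"], s=14, c=colors, linewidths=0)
    if "key" in degs:
        for _, row in degs[degs["key"]].iterrows():
            ax.annotate(row["gene"], (row["probability"], row["betweenness"]), fontsize=7)
    ax.set_xlabel("stationary probability")
    ax.set_ylabel("betweenness centrality")
    return ax
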