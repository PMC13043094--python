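"""Figure helpers: PCA score plots, WE-WE scatter, trend grid."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_GROUP_COLORS = {"STR": "#c0392b", "NSTR": "#e67e22", "CTRL": "#2980b9",
                 "Adj": "#e67e22", "Dist": "#f1c40f"}


def pca_plot(pca, groups: pd.Series, components=("PC1", "PC3"), path=None):
    cx, cy = components
    fig, ax = plt.subplots(figsize=(5, 5))
    g = groups.reindex(pca.scores.index)
    for grp in pd.unique(g.dropna()):
        m = (g == grp).to_numpy()
        ax.scatter(pca.scores.loc[m, cx], pca.scores.loc[m, cy],
                   label=grp, color=_GROUP_COLORS.get(grp, "gray"), s=30)
    ix, iy = int(cx[2:]) - 1, int(cy[2:]) - 1
    ax.set_xlabel(f"{cx} ({pca.var_explained[ix] * 100:.1f}%)")
    ax.set_ylabel(f"{cy} ({pca.var_explained[iy] * 100:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def we_scatter(combined: pd.DataFrame, percentile: float = 0.25, path=None):
    """WE (STRvCTRL) vs WE (STRvNSTR) with percentile threshold lines."""
    wide = combined.pivot_table(index="protein_id", columns="comparison", values="we")
    de = combined.groupby("protein_id")["combined_de"].any()
    wide = wide.dropna(subset=[c for c in ("STRvCTRL", "STRvNSTR") if c in wide.columns])
    fig, ax = plt.subplots(figsize=(5, 5))
    x = wide.get("STRvCTRL")
    y = wide.get("STRvNSTR")
    if x is None or y is None:
        raise ValueError("need STRvCTRL and STRvNSTR WEs")
    is_de = de.reindex(wide.index).fillna(False)
    ax.scatter(x[~is_de], y[~is_de], s=8, color="lightgray")
    ax.scatter(x[is_de], y[is_de], s=10, color="#c0392b")
    for vals, line in ((x[is_de], ax.axvline), (y[is_de], ax.axhline)):
        if len(vals):
            line(np.quantile(vals.abs(), 1 - percentile), ls=":", color="k", lw=0.8)
    lim = max(abs(np.r_[x, y])) * 1.05
    ax.plot([-lim, lim], [-lim, lim], color="gray", lw=0.6)
    ax.set_xlabel("WE STRvCTRL (log2)")
    ax.set_ylabel("WE STRvNSTR (log2)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def trend_grid(profiles: pd.DataFrame, path=None):
    """Scaled Adj/Dist coordinates over the 16-box CTRL-STR reference grid."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for i in range(5):
        ax.axvline(i * 0.25, color="gray", lw=0.5, ls="--")
        ax.axhline(i * 0.25, color="gray", lw=0.5, ls="--")
    for box in range(1, 17):
        r, c = divmod(box - 1, 4)
        ax.text(c * 0.25 + 0.125, (3 - r) * 0.25 + 0.125, str(box),
                ha="center", va="center", color="lightgray", fontsize=9)
    colors = {"progressive": "#d35400", "adjacent_saturating": "#8e44ad",
              "early_shift": "#16a085", "non_monotone": "gray"}
    for pat, grp in profiles.groupby("pattern"):
        ax.scatter(grp["x_adj"], grp["y_dist"], s=14,
                   color=colors.get(pat, "black"), label=pat)
    ax.set_xlabel("Adj (scaled, CTRL=0 STR=1)")
    ax.set_ylabel("Dist (scaled)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
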