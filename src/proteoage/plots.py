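"""Diagnostic figures: volcano, scree, stability curves, cluster heatmap.

All functions take fitted results and return a matplotlib Figure; layout is
utilitarian and deliberately minimal.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusteringResults, StabilityResults
from .diffexp import DEResults


def volcano(result: DEResults, fc_lines: float = 1.0, label_top: int = 15):
    """Volcano plot: log2 fold change vs -log10 BH-adjusted p."""
    t = result.table
    fig, ax = plt.subplots(figsize=(6, 5))
    sig_up = t["significant"] & (t["direction"] == "up")
    sig_dn = t["significant"] & (t["direction"] == "down")
    ax.scatter(t.loc[~t["significant"], "log2_fc"],
               t.loc[~t["significant"], "neg_log10_p_adj"],
               s=6, c="0.7", label="not significant")
    ax.scatter(t.loc[sig_up, "log2_fc"], t.loc[sig_up, "neg_log10_p_adj"],
               s=8, c="firebrick", label="up")
    ax.scatter(t.loc[sig_dn, "log2_fc"], t.loc[sig_dn, "neg_log10_p_adj"],
               s=8, c="steelblue", label="down")
    ax.axhline(-np.log10(result.spec.alpha_fdr), ls=":", c="k", lw=0.8)
    for x in (-fc_lines, fc_lines):
        ax.axvline(x, ls=":", c="k", lw=0.8)
    for _, row in t.nsmallest(label_top, "p_adj").iterrows():
        if row["significant"]:
            ax.annotate(row["assay"], (row["log2_fc"], row["neg_log10_p_adj"]),
                        fontsize=6)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(f"{result.spec.group_a} vs {result.spec.group_b}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def scree(model: ClusteringResults, k_max: int = 20):
    """Merge-height scree with the chosen cut marked."""
    h = np.sort(model.merge_heights)[::-1][: k_max + 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(2, len(h) + 2), h, "o-", ms=4)
    ax.axvline(model.k, ls="--", c="firebrick",
               label=f"k = {model.k}")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("merge height")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def stability_curves(result: StabilityResults):
    """Normalized stability score per subsampling proportion."""
    scores = result.scores()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(scores["proportion"], scores["normalized_score"], "o-")
    ax.set_xlabel("subsampling proportion")
    ax.set_ylabel("normalized stability score")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    return fig


def cluster_heatmap(model: ClusteringResults, cohort=None):
    """Proteins x samples heatmap ordered by cluster; matched OC-OP pairs
    adjacent when a cohort table is given."""
    data = model.matrix.data.T  # proteins x samples
    order = model.labels.sort_values().index
    data = data.loc[order]
    if cohort is not None:
        cols = list(cohort.sort_values(["group", "pair_id"],
                                       na_position="first")["sample_id"])
        data = data[[c for c in cols if c in data.columns]]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5, interpolation="nearest")
    # cluster boundaries
    sizes = model.labels.loc[order].to_numpy()
    edges = np.flatnonzero(np.diff(sizes)) + 0.5
    for y in edges:
        ax.axhline(y, c="k", lw=0.5)
    ax.set_xlabel("samples")
    ax.set_ylabel(f"proteins ({model.k} clusters)")
    fig.colorbar(im, ax=ax, shrink=0.7, label="z-scored NPX")
    fig.tight_layout()
    return fig
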