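"""Figure rendering from a pipeline run directory.

Reads the TSV artifacts written by :func:`sclnc.pipeline.run_pipeline` and
renders the standard report panels: sample distance heatmap, PCA embedding,
MA plots per contrast, lncRNA length distribution and the cis-pair
fold-change scatter.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _save(fig: plt.Figure, run_dir: str, stem: str, formats: list[str]) -> list[str]:
    written = []
    for ext in formats:
        path = os.path.join(run_dir, f"{stem}.{ext}")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        written.append(path)
    plt.close(fig)
    return written


def render_report(run_dir: str, formats: list[str] | None = None) -> list[str]:
    formats = formats or ["png"]
    written: list[str] = []

    dist_path = os.path.join(run_dir, "distance_matrix.tsv")
    if os.path.exists(dist_path):
        dist = pd.read_csv(dist_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(dist.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(dist)), dist.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(dist)), dist.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="Euclidean distance (log2 norm counts)")
        ax.set_title("Sample distances")
        written += _save(fig, run_dir, "distance_heatmap", formats)

    pca_path = os.path.join(run_dir, "pca.tsv")
    if os.path.exists(pca_path):
        pca = pd.read_csv(pca_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4.2))
        groups = [sid.split(":")[0].rsplit("_", 1)[0] for sid in pca.index]
        for group in sorted(set(groups)):
            mask = [g == group for g in groups]
            ax.scatter(pca.loc[mask, "PC1"], pca.loc[mask, "PC2"], label=group, s=40)
        ev = pca["explained_variance"].dropna().to_numpy()
        ax.set_xlabel(f"PC1 ({ev[0] * 100:.1f}%)" if len(ev) > 0 else "PC1")
        ax.set_ylabel(f"PC2 ({ev[1] * 100:.1f}%)" if len(ev) > 1 else "PC2")
        ax.legend(fontsize=7)
        ax.set_title("PCA of pseudobulk samples")
        written += _save(fig, run_dir, "pca", formats)

    for contrast in ("cell_type", "timepoint"):
        ma_path = os.path.join(run_dir, f"ma_{contrast}.tsv")
        if not os.path.exists(ma_path):
            continue
        ma = pd.read_csv(ma_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        sig = ma["significant"].astype(bool)
        ax.scatter(ma.loc[~sig, "log2_baseMean"], ma.loc[~sig, "log2FoldChange"],
                   s=6, c="grey", alpha=0.6, label="not significant")
        ax.scatter(ma.loc[sig, "log2_baseMean"], ma.loc[sig, "log2FoldChange"],
                   s=8, c="crimson", label="padj < alpha")
        ax.axhline(0, lw=0.8, c="k")
        ax.set_xlabel("log2 baseMean")
        ax.set_ylabel("log2 fold change")
        ax.set_title(f"MA plot: {contrast}")
        ax.legend(fontsize=7)
        written += _save(fig, run_dir, f"ma_{contrast}", formats)

    hist_path = os.path.join(run_dir, "length_histogram.tsv")
    if os.path.exists(hist_path):
        hist = pd.read_csv(hist_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        labels = [
            f"{int(s)}-{'inf' if np.isinf(e) else int(e)}"
            for s, e in zip(hist["bin_start"], hist["bin_end"])
        ]
        ax.bar(range(len(hist)), hist["count"], color="steelblue")
        ax.set_xticks(range(len(hist)), labels, rotation=45, fontsize=7)
        ax.set_xlabel("mature length (bp)")
        ax.set_ylabel("expressed lncRNAs")
        ax.set_title("lncRNA length distribution")
        written += _save(fig, run_dir, "length_distribution", formats)

    cis_path = os.path.join(run_dir, "cis_pairs.tsv")
    if os.path.exists(cis_path):
        pairs = pd.read_csv(cis_path, sep="\t")
        if len(pairs):
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            ax.scatter(pairs["lnc_lfc"], pairs["coding_lfc"], s=14, c="darkorange")
            ax.axhline(0, lw=0.8, c="k")
            ax.axvline(0, lw=0.8, c="k")
            ax.set_xlabel("lncRNA log2FC")
            ax.set_ylabel("coding partner log2FC")
            ax.set_title("cis-pair fold changes (<=5 kb)")
            written += _save(fig, run_dir, "cis_pairs", formats)

    if not written:
        raise ValueError(f"no report inputs found in {run_dir}")
    return written
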