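"""Genomic-context characterization of lncRNAs and descriptive summaries.

A lncRNA is called *intragenic* when its gene span overlaps, or lies within
5 kb of, the span of a protein-coding gene on the same chromosome — the
proximity convention used for cis-pair analysis — and *intergenic*
otherwise.  For each intragenic lncRNA the nearest coding gene forms a cis
pair whose two log2 fold changes (from a shared contrast) feed the Pearson
correlation of cis regulatory concordance.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .annotation import GeneModel, GenomeAnnotation
from .diffexp import DETable

DEFAULT_WINDOW = 5000


@dataclass
class CisPair:
    """A lncRNA and its nearest protein-coding gene on the same chromosome.

    ``gap_bp`` is the span gap (0 iff spans overlap); ``signed_offset`` is
    negative when the lncRNA lies upstream of the coding gene in the coding
    gene's orientation.  LFC fields are filled from a shared DE contrast.
    """

    lnc_id: str
    coding_id: str
    gap_bp: int
    signed_offset: int
    relation: str  # overlapping_sense | overlapping_antisense | upstream | downstream
    lnc_lfc: float | None = None
    coding_lfc: float | None = None


class CodingIndex:
    """Sorted per-chromosome coding gene spans for nearest-gap queries."""

    def __init__(self, ann: GenomeAnnotation) -> None:
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in ann.by_biotype("coding"):
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for genes in self._by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
        self._starts = {c: [g.start for g in gs] for c, gs in self._by_chrom.items()}
        # prefix_max_end[j] = furthest right end among genes[0..j]; bounds the
        # leftward scan even when spans overlap each other
        self._prefix_max_end: dict[str, list[int]] = {}
        for c, gs in self._by_chrom.items():
            acc, prefix = 0, []
            for g in gs:
                acc = max(acc, g.end)
                prefix.append(acc)
            self._prefix_max_end[c] = prefix

    def nearest(self, chrom: str, start: int, end: int) -> tuple[GeneModel, int] | None:
        """Nearest coding gene to a 0-based half-open span and its gap in bp.

        Ties on gap are broken by lexicographically smallest gene_id, making
        the classification deterministic.
        """
        genes = self._by_chrom.get(chrom)
        if not genes:
            return None
        i = bisect_left(self._starts[chrom], start)
        prefix_end = self._prefix_max_end[chrom]
        best: tuple[int, str, GeneModel] | None = None
        # leftward: stop only when no remaining gene can beat (or tie) best
        for j in range(i - 1, -1, -1):
            if best is not None and start - prefix_end[j] > best[0]:
                break
            g = genes[j]
            gap = _span_gap(start, end, g.start, g.end)
            if best is None or (gap, g.gene_id) < (best[0], best[1]):
                best = (gap, g.gene_id, g)
        # rightward: starts are sorted, so gaps grow monotonically past `end`
        for j in range(i, len(genes)):
            g = genes[j]
            if best is not None and g.start - end > best[0]:
                break
            gap = _span_gap(start, end, g.start, g.end)
            if best is None or (gap, g.gene_id) < (best[0], best[1]):
                best = (gap, g.gene_id, g)
        if best is None:
            return None
        return best[2], best[0]


def _span_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """bp gap between two 0-based half-open spans; 0 when they overlap."""
    if s1 < e2 and s2 < e1:
        return 0
    return max(s2 - e1, s1 - e2)


def classify_genomic_context(
    lnc: GeneModel,
    coding_index: CodingIndex,
    window: int = DEFAULT_WINDOW,
) -> tuple[str, CisPair | None]:
    """Classify one lncRNA as intragenic (span gap <= window bp to the
    nearest coding gene, overlap included) or intergenic.

    Returns the class and a :class:`CisPair` skeleton (LFCs unfilled);
    the pair is None when the chromosome carries no coding gene.
    """
    hit = coding_index.nearest(lnc.chrom, lnc.start, lnc.end)
    if hit is None:
        return "intergenic", None
    coding, gap = hit
    if gap == 0:
        relation = (
            "overlapping_sense" if lnc.strand == coding.strand else "overlapping_antisense"
        )
        signed = 0
    else:
        # upstream = 5' of the coding gene in its own orientation
        lnc_is_left = lnc.end <= coding.start
        upstream = lnc_is_left if coding.strand == "+" else not lnc_is_left
        relation = "upstream" if upstream else "downstream"
        signed = -gap if upstream else gap
    pair = CisPair(
        lnc_id=lnc.gene_id,
        coding_id=coding.gene_id,
        gap_bp=gap,
        signed_offset=signed,
        relation=relation,
    )
    cls = "intragenic" if gap <= window else "intergenic"
    return cls, pair


def build_cis_pairs(
    ann: GenomeAnnotation,
    window: int = DEFAULT_WINDOW,
    lnc_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Classify every lncRNA and return the per-lncRNA context table."""
    index = CodingIndex(ann)
    lncs = ann.by_biotype("lncRNA")
    if lnc_ids is not None:
        wanted = set(lnc_ids)
        lncs = [g for g in lncs if g.gene_id in wanted]
    rows = []
    for lnc in sorted(lncs, key=lambda g: g.gene_id):
        cls, pair = classify_genomic_context(lnc, index, window=window)
        rows.append(
            {
                "lnc_id": lnc.gene_id,
                "class": cls,
                "coding_id": pair.coding_id if pair else None,
                "gap_bp": pair.gap_bp if pair else None,
                "signed_offset": pair.signed_offset if pair else None,
                "relation": pair.relation if pair else None,
                "strand": lnc.strand,
                "mature_length": lnc.mature_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "class", "coding_id", "gap_bp", "signed_offset",
                 "relation", "strand", "mature_length"],
    )


def attach_fold_changes(
    pairs: pd.DataFrame,
    de: DETable,
    significant_only: bool = True,
    require: str = "both",
) -> pd.DataFrame:
    """Fill lnc_lfc / coding_lfc from one shared contrast.

    Only intragenic pairs are kept.  With ``significant_only`` the DE
    significance filter (padj < alpha of the DETable) is applied to the
    lncRNA, the coding gene, or both partners per ``require``.  Pairs where
    either partner was not tested are dropped (tallied in the ``dropped``
    attr).
    """
    if require not in ("both", "lnc", "coding"):
        raise ValueError(f"require must be both|lnc|coding, got {require!r}")
    lut = de.table.set_index("gene_id")
    out = pairs[pairs["class"] == "intragenic"].copy()
    n_before = len(out)
    tested = out["lnc_id"].isin(lut.index) & out["coding_id"].isin(lut.index)
    out = out[tested]
    out["lnc_lfc"] = lut.loc[out["lnc_id"], "log2FoldChange"].to_numpy()
    out["coding_lfc"] = lut.loc[out["coding_id"], "log2FoldChange"].to_numpy()
    out = out[out["lnc_lfc"].notna() & out["coding_lfc"].notna()]
    if significant_only:
        lnc_sig = lut.loc[out["lnc_id"], "significant"].to_numpy(dtype=bool)
        cod_sig = lut.loc[out["coding_id"], "significant"].to_numpy(dtype=bool)
        mask = {
            "both": lnc_sig & cod_sig,
            "lnc": lnc_sig,
            "coding": cod_sig,
        }[require]
        out = out[mask]
    out = out.reset_index(drop=True)
    out.attrs["dropped"] = n_before - len(out)
    return out


def cis_correlation(pairs: pd.DataFrame) -> tuple[float, int, pd.DataFrame]:
    """Pearson r between lnc and coding log2 fold changes over cis pairs.

    Returns (r, n_pairs, per-pair table); r is NaN when fewer than 3 pairs
    remain or either coordinate has zero variance.  The table carries the
    fraction of sign-concordant pairs in its ``sign_concordance`` attr.
    """
    table = pairs[["lnc_id", "coding_id", "gap_bp", "lnc_lfc", "coding_lfc"]].copy()
    n = len(table)
    x = table["lnc_lfc"].to_numpy(dtype=float)
    y = table["coding_lfc"].to_numpy(dtype=float)
    if n >= 1:
        table.attrs["sign_concordance"] = float(np.mean(np.sign(x) == np.sign(y)))
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), n, table
    r = float(stats.pearsonr(x, y).statistic)
    return r, n, table


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def strand_tally(expressed_lncs: list[GeneModel]) -> tuple[int, int]:
    """(n_sense, n_antisense) over already-expression-filtered lncRNAs."""
    n_sense = sum(1 for g in expressed_lncs if g.strand == "+")
    return n_sense, len(expressed_lncs) - n_sense


def length_distribution(
    expressed_lncs: list[GeneModel],
    bins: np.ndarray | list[float] | None = None,
    length: str = "mature",
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of lncRNA lengths (exon-union by default, span optionally)."""
    if length not in ("mature", "span"):
        raise ValueError(f"length must be mature|span, got {length!r}")
    values = np.array(
        [g.mature_length if length == "mature" else g.span_length for g in expressed_lncs]
    )
    if bins is None:
        bins = np.array([0, 300, 600, 1000, 1500, 2500, 5000, 10000, np.inf])
    counts, edges = np.histogram(values, bins=np.asarray(bins, dtype=float))
    return counts, edges


def expressed_genes(
    matrix_base_means: pd.Series, ann: GenomeAnnotation, threshold: float = 1.0
) -> dict[str, list[GeneModel]]:
    """Genes at or above the baseMean expression threshold, split by biotype."""
    out: dict[str, list[GeneModel]] = {"coding": [], "lncRNA": [], "other": []}
    for gid, bm in matrix_base_means.items():
        if bm >= threshold and gid in ann:
            out[ann[gid].biotype].append(ann[gid])
    return out


def distance_matrix(norm_counts: np.ndarray) -> np.ndarray:
    """Euclidean distances between samples on the log2(normalized + 1) scale.

    Input is the genes x samples normalized count matrix; output is the
    samples x samples symmetric distance matrix with zero diagonal.
    """
    logged = np.log2(np.asarray(norm_counts, dtype=float) + 1.0)
    if logged.shape[1] < 2:
        raise ValueError("distance matrix needs >=2 samples")
    return squareform(pdist(logged.T, metric="euclidean"))


def pca_embedding(
    norm_counts: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Sample PCA of log2(normalized + 1) expression, genes centered.

    Returns (coordinates (samples, k), explained variance fractions).  Each
    component's sign is fixed so its largest-magnitude gene loading is
    positive, making the embedding deterministic.  When fewer non-trivial
    components exist than requested, the result is truncated.
    """
    logged = np.log2(np.asarray(norm_counts, dtype=float) + 1.0)
    n_genes, n_samples = logged.shape
    centered = logged - logged.mean(axis=1, keepdims=True)
    k = min(n_components, n_samples)
    if k < n_components:
        import warnings

        warnings.warn(
            f"only {n_samples} samples; truncating PCA to {k} components",
            stacklevel=2,
        )
    # SVD of genes x samples centered matrix: columns of V are sample directions
    u, sing, vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]
    coords = (vt[:k, :] * sing[:k, np.newaxis]).T
    total_var = float(np.sum(sing**2))
    explained = (sing[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    if total_var == 0:
        coords = np.zeros((n_samples, k))
    return coords, explained


def ma_table(de: DETable) -> pd.DataFrame:
    """Per-gene (log2 baseMean, log2FC, significant) for MA plotting."""
    t = de.table
    with np.errstate(divide="ignore"):
        log2_bm = np.log2(t["baseMean"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "log2_baseMean": log2_bm,
            "log2FoldChange": t["log2FoldChange"],
            "significant": t["significant"],
        }
    )
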