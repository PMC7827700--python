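"""Strand-specific read-to-gene assignment over exon unions and count matrices.

Counting follows the forward-strand convention of 3' single-cell chemistry:
a read is assigned to a gene only when its alignment strand matches the
annotated gene strand (``strandness="forward"``).  A read overlapping the
exon unions of two or more strand-compatible genes is ambiguous and
discarded, never fractionally split.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .reads import ReadRecord, SampleInfo

OUTCOMES = ("assigned", "ambiguous", "no_feature", "strand_mismatch")


class AssignmentOutcome(NamedTuple):
    """Mutually exclusive fate of one routed read."""

    status: str  # one of OUTCOMES
    gene_id: str | None = None


def _block_overlap_bp(
    blocks: Iterable[tuple[int, int]], exons: Iterable[tuple[int, int]]
) -> int:
    total = 0
    for bs, be in blocks:
        for es, ee in exons:
            total += max(0, min(be, ee) - max(bs, es))
    return total


def assign_read(
    read: ReadRecord,
    ann: GenomeAnnotation,
    strandness: str = "forward",
    min_overlap: int = 1,
) -> AssignmentOutcome:
    """Assign one read to a gene by exon-union overlap and strand.

    Candidates are genes whose exon union overlaps at least ``min_overlap``
    bp of the read blocks and whose strand is compatible under
    ``strandness`` (forward: same strand; reverse: opposite; unstranded:
    any).  Exactly one candidate -> assigned; two or more -> ambiguous; none
    but an incompatible-strand exon overlap exists -> strand_mismatch;
    otherwise no_feature.
    """
    if strandness not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"unknown strandness {strandness!r}")
    touched = ann.query_blocks(read.chrom, read.blocks)
    if min_overlap > 1:
        touched = {
            gid
            for gid in touched
            if _block_overlap_bp(read.blocks, ann[gid].exons) >= min_overlap
        }
    if strandness == "unstranded":
        compatible = touched
    else:
        want_same = strandness == "forward"
        compatible = {
            gid for gid in touched if (ann[gid].strand == read.strand) == want_same
        }
    if len(compatible) == 1:
        return AssignmentOutcome("assigned", next(iter(compatible)))
    if len(compatible) >= 2:
        return AssignmentOutcome("ambiguous")
    if touched:
        return AssignmentOutcome("strand_mismatch")
    return AssignmentOutcome("no_feature")


def count_partition(
    reads: Iterable[ReadRecord],
    ann: GenomeAnnotation,
    strandness: str = "forward",
    min_overlap: int = 1,
    umi_dedup: bool = False,
) -> tuple[Counter, Counter]:
    """Count assigned reads per gene for one pseudobulk sample.

    Returns ``(counts, tallies)`` where tallies holds one entry per
    :data:`OUTCOMES` status and conserves the input total.  With
    ``umi_dedup`` records collapsing to an already-seen
    (gene, barcode, UMI) triple are tallied as ``umi_duplicate`` instead of
    counted.
    """
    counts: Counter = Counter()
    tallies: Counter = Counter({status: 0 for status in OUTCOMES})
    seen_umis: set[tuple[str, str | None, str | None]] = set()
    for read in reads:
        outcome = assign_read(read, ann, strandness=strandness, min_overlap=min_overlap)
        if outcome.status == "assigned":
            if umi_dedup and read.umi is not None:
                key = (outcome.gene_id, read.cell_barcode, read.umi)
                if key in seen_umis:
                    tallies["umi_duplicate"] += 1
                    continue
                seen_umis.add(key)
            counts[outcome.gene_id] += 1
        tallies[outcome.status] += 1
    return counts, tallies


@dataclass
class CountMatrix:
    """Genes x pseudobulk samples integer counts with sample metadata.

    Gene and sample order are lexicographic, so the matrix built from a set
    of per-sample count vectors is independent of input order.
    """

    gene_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray  # shape (genes, samples), dtype int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def sample_metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [s.cluster for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "cell_type": [s.cell_type for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        keep = [gid for gid in self.gene_ids if gid in set(gene_ids)]
        idx = [self.gene_ids.index(g) for g in keep]
        return CountMatrix(keep, list(self.samples), self.counts[idx, :])

    def write_tsv(self, path: str) -> None:
        df = self.to_dataframe()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str, metadata: pd.DataFrame) -> "CountMatrix":
        """Load a counts TSV; ``metadata`` supplies cluster/timepoint/cell_type
        per sample_id column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples = [
            SampleInfo(
                sample_id=sid,
                cluster=str(metadata.loc[sid, "cluster"]),
                timepoint=str(metadata.loc[sid, "timepoint"]),
                cell_type=str(metadata.loc[sid, "cell_type"]),
            )
            for sid in df.columns
        ]
        return cls(list(df.index), samples, df.to_numpy(dtype=np.int64))

    def write_mtx(self, prefix: str) -> None:
        """MatrixMarket triplet + row/column sidecar files."""
        from scipy import io as scipy_io
        from scipy import sparse

        scipy_io.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(self.counts))
        with open(f"{prefix}.rows.tsv", "w") as fh:
            fh.write("\n".join(self.gene_ids) + "\n")
        with open(f"{prefix}.cols.tsv", "w") as fh:
            fh.write("\n".join(self.sample_ids) + "\n")


def build_count_matrix(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    ann: GenomeAnnotation,
    samples: Iterable[SampleInfo],
) -> CountMatrix:
    """Assemble per-sample count vectors into a deterministic CountMatrix.

    All annotation genes are retained as rows (zero-count rows included);
    rows and columns are sorted lexicographically.  A sample name collision
    is an error.
    """
    sample_list = sorted(samples, key=lambda s: s.sample_id)
    ids = [s.sample_id for s in sample_list]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"sample name collision: {dup}")
    gene_ids = sorted(ann.genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(gene_ids), len(sample_list)), dtype=np.int64)
    for j, sample in enumerate(sample_list):
        for gene_id, n in per_sample_counts.get(sample.sample_id, {}).items():
            if gene_id not in gene_pos:
                raise ValueError(f"counted gene {gene_id!r} absent from annotation")
            counts[gene_pos[gene_id], j] = n
    return CountMatrix(gene_ids, sample_list, counts)


def count_all_partitions(
    partitions: Mapping[str, list[ReadRecord]],
    ann: GenomeAnnotation,
    samples: Iterable[SampleInfo],
    strandness: str = "forward",
    min_overlap: int = 1,
    umi_dedup: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count every pseudobulk partition and assemble matrix + outcome tallies."""
    per_sample: dict[str, Counter] = {}
    tally_rows = []
    for sample_id in sorted(partitions):
        counts, tallies = count_partition(
            partitions[sample_id],
            ann,
            strandness=strandness,
            min_overlap=min_overlap,
            umi_dedup=umi_dedup,
        )
        per_sample[sample_id] = counts
        tally_rows.append({"sample_id": sample_id, **tallies})
    matrix = build_count_matrix(per_sample, ann, samples)
    tally_df = pd.DataFrame(tally_rows).set_index("sample_id") if tally_rows else pd.DataFrame()
    return matrix, tally_df
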