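"""Streaming of barcoded alignments and partitioning into cluster pseudobulks.

Mirrors the per-cluster BAM subsetting step of 10x-style pipelines: cell
barcodes (CB tag by default) route each primary alignment to the pseudobulk
sample of its cluster x timepoint, with every dropped read tallied by reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam

# CIGAR operation codes (BAM numeric encoding)
_REF_ADVANCE_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N splits blocks
_NO_REF = {1, 4, 5, 6}  # I, S, H, P consume no reference


@dataclass
class ReadRecord:
    """One mapped alignment reduced to what counting needs."""

    read_id: str
    chrom: str
    strand: str  # from SAM flag 0x10
    blocks: list[tuple[int, int]]  # 0-based half-open reference intervals
    cell_barcode: str | None = None
    umi: str | None = None
    nh: int | None = None
    flags: int = 0


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    cluster: str
    timepoint: str
    cell_type: str


class ClusterMap:
    """barcode -> (cluster, timepoint, cell_type); defines pseudobulk samples."""

    def __init__(self) -> None:
        self._assignments: dict[str, SampleInfo] = {}

    @staticmethod
    def sample_id_for(cluster: str, timepoint: str) -> str:
        return f"{cluster}:{timepoint}"

    def add(self, barcode: str, cluster: str, timepoint: str, cell_type: str | None = None) -> None:
        info = SampleInfo(
            sample_id=self.sample_id_for(cluster, timepoint),
            cluster=cluster,
            timepoint=timepoint,
            cell_type=cell_type if cell_type is not None else cluster,
        )
        existing = self._assignments.get(barcode)
        if existing is not None and existing != info:
            raise ValueError(
                f"barcode {barcode!r} assigned to both {existing.sample_id} "
                f"and {info.sample_id}"
            )
        self._assignments[barcode] = info

    def get(self, barcode: str) -> SampleInfo | None:
        return self._assignments.get(barcode)

    def __len__(self) -> int:
        return len(self._assignments)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._assignments

    def barcodes(self) -> list[str]:
        return sorted(self._assignments)

    def samples(self) -> list[SampleInfo]:
        """All pseudobulk samples, sorted by sample_id (deterministic)."""
        return sorted(set(self._assignments.values()), key=lambda s: s.sample_id)

    def sample_metadata(self) -> pd.DataFrame:
        """One row per pseudobulk sample, indexed by sample_id."""
        rows = [
            {
                "sample_id": s.sample_id,
                "cluster": s.cluster,
                "timepoint": s.timepoint,
                "cell_type": s.cell_type,
                "n_cells": sum(
                    1 for a in self._assignments.values() if a.sample_id == s.sample_id
                ),
            }
            for s in self.samples()
        ]
        return pd.DataFrame(rows).set_index("sample_id")


def load_cluster_map(path: str) -> ClusterMap:
    """Load a barcode assignment TSV with columns barcode, cluster, timepoint.

    An optional ``cell_type`` column groups clusters for the cell-type
    contrast; when absent the cluster label itself is the cell-type group.
    Duplicated rows with identical assignment are idempotent; a barcode with
    conflicting assignments is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["barcode", "cluster", "timepoint"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"cluster map {path} is missing required column {col!r}")
    cmap = ClusterMap()
    has_ct = "cell_type" in df.columns
    for row in df.itertuples(index=False):
        cmap.add(
            row.barcode,
            row.cluster,
            row.timepoint,
            getattr(row, "cell_type") if has_ct else None,
        )
    return cmap


@dataclass
class PartitionSummary:
    """Read accounting: assigned per sample plus dropped tallies by reason.

    Invariant: total input records = sum(assigned) + sum(dropped).
    """

    assigned: Counter = field(default_factory=Counter)  # sample_id -> reads
    dropped: Counter = field(default_factory=Counter)  # reason -> reads

    REASONS = (
        "no_barcode",
        "unassigned_barcode",
        "unmapped",
        "secondary_or_supplementary",
        "multimapped",
    )

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_dropped

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": f"assigned:{k}", "reads": v} for k, v in sorted(self.assigned.items())]
        rows += [{"category": f"dropped:{r}", "reads": self.dropped.get(r, 0)} for r in self.REASONS]
        return pd.DataFrame(rows)


def blocks_from_cigar(cigartuples: Iterable[tuple[int, int]], pos: int, read_id: str) -> list[tuple[int, int]]:
    """Walk a CIGAR into 0-based half-open reference blocks.

    M/=/X and D extend the current block; N closes it and skips the gap;
    I/S/H/P consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cursor = pos
    block_start = pos
    open_block = False
    for op, length in cigartuples:
        if op in _REF_ADVANCE_IN_BLOCK:
            if not open_block:
                block_start = cursor
                open_block = True
            cursor += length
        elif op == _REF_SKIP:
            if open_block:
                blocks.append((block_start, cursor))
                open_block = False
            cursor += length
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"read {read_id}: unknown CIGAR operation code {op}")
    if open_block:
        blocks.append((block_start, cursor))
    return blocks


def stream_alignments(
    path: str,
    barcode_tag: str = "CB",
    umi_tag: str = "UB",
    min_mapq: int = 0,
    summary: PartitionSummary | None = None,
) -> Iterator[ReadRecord]:
    """Yield mapped primary alignments as :class:`ReadRecord`.

    Unmapped, secondary (0x100) and supplementary (0x800) records are skipped
    and tallied in ``summary`` when one is provided.  No MAPQ filter is
    applied by default.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                if summary is not None:
                    summary.dropped["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                if summary is not None:
                    summary.dropped["secondary_or_supplementary"] += 1
                continue
            if min_mapq and aln.mapping_quality < min_mapq:
                if summary is not None:
                    summary.dropped["low_mapq"] += 1
                continue
            blocks = blocks_from_cigar(
                aln.cigartuples or [], aln.reference_start, aln.query_name
            )
            yield ReadRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                blocks=blocks,
                cell_barcode=aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag) else None,
                umi=aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else None,
                nh=aln.get_tag("NH") if aln.has_tag("NH") else None,
                flags=aln.flag,
            )


def partition_by_cluster(
    reads: Iterable[ReadRecord],
    cmap: ClusterMap,
    summary: PartitionSummary | None = None,
    drop_multimapped: bool = True,
) -> tuple[dict[str, list[ReadRecord]], PartitionSummary]:
    """Route each read to the pseudobulk sample of its barcode.

    Reads without a barcode tag, with a barcode absent from the map, or with
    NH > 1 (when ``drop_multimapped``) are dropped and tallied; drops are
    never fatal.  Every read lands in exactly one sample.
    """
    if summary is None:
        summary = PartitionSummary()
    partitions: dict[str, list[ReadRecord]] = {
        s.sample_id: [] for s in cmap.samples()
    }
    for read in reads:
        if drop_multimapped and read.nh is not None and read.nh > 1:
            summary.dropped["multimapped"] += 1
            continue
        if read.cell_barcode is None:
            summary.dropped["no_barcode"] += 1
            continue
        info = cmap.get(read.cell_barcode)
        if info is None:
            summary.dropped["unassigned_barcode"] += 1
            continue
        partitions[info.sample_id].append(read)
        summary.assigned[info.sample_id] += 1
    return partitions, summary
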