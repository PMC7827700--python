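"""Gene annotation handling: GTF parsing, gene models, interval queries.

Gene models follow the GENCODE GTF dialect: ``gene`` records carry
``gene_id``/``gene_name``/``gene_type`` (or ``gene_biotype``) attributes and
``exon`` records attach exon intervals to their parent gene.  Coordinates on
disk are 1-based inclusive; everything held in memory is 0-based half-open,
and public reporting accessors convert back to 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: raw GTF biotype values collapsed into the internal lncRNA class.  The
#: legacy values were folded into ``lncRNA`` in recent GENCODE releases but
#: still occur in older annotation files.
_LNC_BIOTYPES = {"lncRNA", "antisense", "lincRNA"}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; message carries the line number."""


def classify_biotype(raw: str) -> str:
    """Map a raw GTF biotype string to {coding, lncRNA, other}."""
    if raw == "protein_coding":
        return "coding"
    if raw in _LNC_BIOTYPES:
        return "lncRNA"
    return "other"


@dataclass
class GeneModel:
    """One gene: strand, biotype and the union of its exon intervals.

    ``start``/``end`` and ``exons`` are 0-based half-open; exons are kept
    sorted and merged so that ``mature_length`` is simply their total size.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    raw_biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.raw_biotype:
            self.raw_biotype = {"coding": "protein_coding", "lncRNA": "lncRNA"}.get(
                self.biotype, self.biotype
            )
        self.exons = merge_intervals(self.exons)
        if self.exons:
            self.start = min(self.start, self.exons[0][0])
            self.end = max(self.end, self.exons[-1][1])

    # -- 1-based inclusive reporting accessors ------------------------------
    @property
    def span_start(self) -> int:
        return self.start + 1

    @property
    def span_end(self) -> int:
        return self.end

    @property
    def exons_1based(self) -> list[tuple[int, int]]:
        return [(s + 1, e) for s, e in self.exons]

    @property
    def mature_length(self) -> int:
        """Length of the exon union (what strand-specific counting sees)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise ValueError(f"gene {self.gene_id}: span does not cover exons")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge half-open intervals; duplicates and order are irrelevant."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class GenomeAnnotation:
    """Collection of gene models with per-chromosome interval indexes.

    Two indexes are kept per chromosome: one over exon intervals (used by
    read assignment) and one over whole gene spans (used by the genomic
    context classifier).  Every indexed interval maps back to one gene_id.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self.genes: dict[str, GeneModel] = {}
        self._exon_index: dict[str, IntervalTree] = {}
        self._span_index: dict[str, IntervalTree] = {}
        self._warned_chroms: set[str] = set()
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        gene.validate()
        self.genes[gene.gene_id] = gene
        spans = self._span_index.setdefault(gene.chrom, IntervalTree())
        spans.addi(gene.start, gene.end, gene.gene_id)
        exons = self._exon_index.setdefault(gene.chrom, IntervalTree())
        for s, e in gene.exons:
            exons.addi(s, e, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def chromosomes(self) -> set[str]:
        return set(self._span_index)

    def by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == biotype]

    def merged_with(self, other: "GenomeAnnotation") -> "GenomeAnnotation":
        return GenomeAnnotation(list(self.genes.values()) + list(other.genes.values()))

    # -- queries ------------------------------------------------------------
    def query_overlaps(
        self, chrom: str, start: int, end: int, level: str = "exon"
    ) -> set[str]:
        """Genes overlapping a 1-based inclusive query window by >=1 bp.

        ``level`` selects the exon-union index or the gene-span index.  An
        unknown chromosome yields an empty set (logged once per chromosome),
        because annotation/alignment chromosome dialect mismatches should
        surface as warnings, not crashes.
        """
        if start > end:
            raise ValueError(f"query start {start} > end {end}")
        if level not in ("exon", "span"):
            raise ValueError(f"unknown query level {level!r}")
        index = self._exon_index if level == "exon" else self._span_index
        tree = index.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                log.warning("query on unknown chromosome %r (reported once)", chrom)
                self._warned_chroms.add(chrom)
            return set()
        return {iv.data for iv in tree.overlap(start - 1, end)}

    def query_blocks(self, chrom: str, blocks: Sequence[tuple[int, int]]) -> set[str]:
        """Genes whose exon union overlaps any 0-based half-open block."""
        tree = self._exon_index.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in blocks:
            hits.update(iv.data for iv in tree.overlap(s, e))
        return hits


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(
    paths: str | Sequence[str],
    biotype_filter: set[str] | None = None,
) -> GenomeAnnotation:
    """Parse one or more GTF files into a :class:`GenomeAnnotation`.

    One gene model per ``gene`` record, with exons attached from ``exon``
    records sharing its gene_id.  Biotype is read from ``gene_type`` with
    ``gene_biotype`` as fallback.  ``biotype_filter``, if given, is a set of
    internal biotype classes ({coding, lncRNA, other}) to retain.

    Raises
    ------
    GtfParseError
        On a malformed line (with file and line number), an exon whose
        gene_id has no gene record, an unknown strand, or a duplicated
        gene_id.
    """
    if isinstance(paths, str):
        paths = [paths]
    genes: dict[str, GeneModel] = {}
    orphan_exons: dict[str, list[tuple[str, int, int, str]]] = {}

    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise GtfParseError(
                        f"{path}:{lineno}: expected 9 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
                if feature not in ("gene", "exon"):
                    continue
                try:
                    start1, end1 = int(start_s), int(end_s)
                except ValueError as exc:
                    raise GtfParseError(f"{path}:{lineno}: bad coordinates") from exc
                if start1 < 1 or end1 < start1:
                    raise GtfParseError(
                        f"{path}:{lineno}: invalid interval {start1}-{end1}"
                    )
                if strand not in ("+", "-"):
                    raise GtfParseError(
                        f"{path}:{lineno}: unknown strand {strand!r}"
                    )
                attributes = _parse_attributes(attrs)
                gene_id = attributes.get("gene_id")
                if not gene_id:
                    raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
                start, end = start1 - 1, end1  # to 0-based half-open
                if feature == "gene":
                    if gene_id in genes:
                        raise GtfParseError(
                            f"{path}:{lineno}: duplicate gene_id {gene_id}"
                        )
                    raw = attributes.get("gene_type") or attributes.get(
                        "gene_biotype", ""
                    )
                    genes[gene_id] = GeneModel(
                        gene_id=gene_id,
                        gene_name=attributes.get("gene_name", gene_id),
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        biotype=classify_biotype(raw),
                        exons=[],
                        raw_biotype=raw or "unknown",
                    )
                else:
                    orphan_exons.setdefault(gene_id, []).append(
                        (chrom, start, end, strand)
                    )

    for gene_id, exon_list in orphan_exons.items():
        gene = genes.get(gene_id)
        if gene is None:
            raise GtfParseError(
                f"exon record references gene_id {gene_id!r} with no gene record"
            )
        gene.exons = merge_intervals(gene.exons + [(s, e) for _, s, e, _ in exon_list])
    # genes with no exon records count over their full span
    for gene in genes.values():
        if not gene.exons:
            gene.exons = [(gene.start, gene.end)]

    selected = [
        g
        for g in genes.values()
        if biotype_filter is None or g.biotype in biotype_filter
    ]
    return GenomeAnnotation(selected)


def write_gtf(ann: GenomeAnnotation, path: str, biotypes: set[str] | None = None) -> None:
    """Write gene + exon records in GENCODE dialect, 1-based inclusive.

    Output order is deterministic (chrom, start, gene_id) so identical
    annotations serialize byte-identically.
    """
    genes = sorted(
        (g for g in ann.genes.values() if biotypes is None or g.biotype in biotypes),
        key=lambda g: (g.chrom, g.start, g.gene_id),
    )
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{g.raw_biotype}"; '
                f'gene_name "{g.gene_name}";'
            )
            fh.write(
                f"{g.chrom}\tsclnc\tgene\t{g.span_start}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s1, e1 in g.exons_1based:
                fh.write(
                    f"{g.chrom}\tsclnc\texon\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def check_chromosome_dialects(ann: GenomeAnnotation, alignment_chroms: set[str]) -> bool:
    """Warn when annotation and alignment chromosome sets are disjoint.

    No silent "chr1" vs "1" normalization is performed; a disjoint set almost
    always means a naming-dialect mismatch the user must resolve upstream.
    """
    shared = ann.chromosomes() & alignment_chroms
    if not shared:
        log.warning(
            "annotation chromosomes %s share no name with alignment chromosomes %s; "
            "check 'chr' prefix dialects",
            sorted(ann.chromosomes())[:5],
            sorted(alignment_chroms)[:5],
        )
        return False
    return True
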