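"""Shared fixtures: tiny annotations, toy SAM inputs, simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from sclnc.annotation import GeneModel, GenomeAnnotation
from sclnc.reads import ReadRecord
from sclnc.synthetic import SimConfig, simulate_annotation, simulate_reads


def make_gene(
    gene_id: str,
    chrom: str = "chr1",
    strand: str = "+",
    exons: list[tuple[int, int]] | None = None,
    biotype: str = "lncRNA",
) -> GeneModel:
    """1-based inclusive exon tuples, converted to the internal convention."""
    exons = exons or [(101, 200)]
    internal = [(s - 1, e) for s, e in exons]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand=strand,
        start=min(s for s, _ in internal),
        end=max(e for _, e in internal),
        biotype=biotype,
        exons=internal,
    )


def make_read(
    read_id: str = "r1",
    chrom: str = "chr1",
    strand: str = "+",
    blocks: list[tuple[int, int]] | None = None,
    barcode: str | None = "BC1",
    nh: int | None = 1,
) -> ReadRecord:
    return ReadRecord(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        blocks=blocks or [(120, 180)],
        cell_barcode=barcode,
        nh=nh,
    )


def random_annotation(
    rng: np.random.Generator,
    n_genes: int = 50,
    n_chroms: int = 2,
    chrom_len: int = 100_000,
) -> GenomeAnnotation:
    """Random small annotation with possibly overlapping multi-exon genes."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - 5000))
        n_exons = int(rng.integers(1, 4))
        exons = []
        cursor = start
        for _ in range(n_exons):
            length = int(rng.integers(100, 800))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(50, 500))
        genes.append(
            GeneModel(
                gene_id=f"G{i:03d}",
                gene_name=f"G{i:03d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=exons[0][0],
                end=exons[-1][1],
                biotype=["coding", "lncRNA", "other"][int(rng.integers(0, 3))],
                exons=exons,
            )
        )
    return GenomeAnnotation(genes)


def random_reads(
    rng: np.random.Generator,
    ann: GenomeAnnotation,
    n_reads: int = 500,
    chrom_len: int = 100_000,
    spliced_fraction: float = 0.3,
) -> list[ReadRecord]:
    """Random reads across the annotated region, mixed spliced/unspliced."""
    chroms = sorted(ann.chromosomes())
    out = []
    for i in range(n_reads):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_len - 2000))
        if rng.random() < spliced_fraction:
            len1 = int(rng.integers(20, 60))
            gap = int(rng.integers(100, 1500))
            len2 = int(rng.integers(20, 60))
            blocks = [(start, start + len1), (start + len1 + gap, start + len1 + gap + len2)]
        else:
            blocks = [(start, start + int(rng.integers(40, 120)))]
        out.append(
            make_read(
                read_id=f"r{i:05d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                blocks=blocks,
            )
        )
    return out


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force, no sclnc internals)
# ---------------------------------------------------------------------------

def oracle_assign(read: ReadRecord, ann: GenomeAnnotation, strandness: str = "forward"):
    """All-pairs exon-overlap scan over every gene; mirrors nothing of the
    indexed implementation."""
    touched = set()
    for gene in ann.genes.values():
        if gene.chrom != read.chrom:
            continue
        hit = False
        for bs, be in read.blocks:
            for es, ee in gene.exons:
                if max(bs, es) < min(be, ee):
                    hit = True
        if hit:
            touched.add(gene.gene_id)
    if strandness == "unstranded":
        compatible = touched
    else:
        same = {g for g in touched if ann[g].strand == read.strand}
        compatible = same if strandness == "forward" else touched - same
    if len(compatible) == 1:
        return ("assigned", next(iter(compatible)))
    if len(compatible) >= 2:
        return ("ambiguous", None)
    if touched:
        return ("strand_mismatch", None)
    return ("no_feature", None)


def oracle_bh(pvalues: list[float]) -> list[float]:
    """Literal BH step-up on a plain Python list."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def oracle_nearest_gap(lnc: GeneModel, coding: list[GeneModel]):
    """Exhaustive nearest-gap scan with lexicographic tie-break."""
    best = None
    for g in coding:
        if g.chrom != lnc.chrom:
            continue
        if lnc.start < g.end and g.start < lnc.end:
            gap = 0
        else:
            gap = max(g.start - lnc.end, lnc.start - g.end)
        key = (gap, g.gene_id)
        if best is None or key < best:
            best = key
    return best  # (gap, gene_id) or None


# ---------------------------------------------------------------------------
# simulated datasets (session-scoped: reused across test modules)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=20260926)


@pytest.fixture(scope="session")
def sim_annotation(sim_cfg):
    return simulate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def sim_data(sim_cfg, sim_annotation):
    ann, truth = sim_annotation
    sam_text, cmap_text, truth = simulate_reads(sim_cfg, ann, truth)
    return ann, sam_text, cmap_text, truth


@pytest.fixture(scope="session")
def sim_dataset_dir(tmp_path_factory, sim_cfg):
    from sclnc.synthetic import simulate_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    paths = simulate_dataset(sim_cfg, str(outdir))
    return paths
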