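"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the tool targets: two ventral
midbrain cell populations (dopaminergic neurons, DA, and floor-plate
progenitors, FP) profiled at three differentiation timepoints with 10x-style
barcoded reads.  It emits a GENCODE-dialect annotation (coding genes tiled
with gaps; lncRNAs planted antisense-overlapping, within 5 kb, or far from a
coding gene), a barcode-to-cluster table, and a coordinate-sorted SAM whose
per-read gene of origin is recorded, so counting, differential expression
and context classification can each be checked against planted truth.

All randomness flows from ``SimConfig.seed``; identical configurations
produce byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .annotation import GeneModel, GenomeAnnotation, write_gtf
from .quantify import CountMatrix
from .reads import SampleInfo

READ_FLAG_REVERSE = 16

#: placement plan tokens for lncRNAs
PLAN_ANTISENSE = "antisense"  # opposite strand inside a coding span (gap 0)
PLAN_NEAR = "near"  # 1..5000 bp from a coding gene -> intragenic
PLAN_FAR = "far"  # >=6000 bp from every coding gene -> intergenic


@dataclass
class ClusterSpec:
    cluster_id: str
    cell_type: str  # DA or FP in the emulated design
    timepoint: str
    n_cells: int


def default_clusters(n_cells: int = 40) -> list[ClusterSpec]:
    """Two cell types x three timepoints, one cluster each."""
    return [
        ClusterSpec(f"{ct}_{tp}", ct, tp, n_cells)
        for ct in ("DA", "FP")
        for tp in ("day16", "day30", "day60")
    ]


@dataclass
class SimConfig:
    """Study-design parameters of the simulator.

    Defaults emulate the target experiment at desk scale: DA vs FP clusters
    across days 16/30/60, forward-strand chemistry, negative-binomial
    per-cell gene counts with planted log2 fold changes on a subset of
    lncRNAs (and their cis coding partners, so cis pairs co-move).
    """

    seed: int
    n_chroms: int = 2
    n_coding: int = 30
    n_lnc: int = 18
    lnc_plan: tuple[str, ...] = (PLAN_ANTISENSE, PLAN_NEAR, PLAN_FAR)
    clusters: list[ClusterSpec] = field(default_factory=default_clusters)
    per_cell_gene_mean: float = 0.5  # mean reads/cell for an abundance-1 gene
    dispersion: float = 0.05  # per-cell NB dispersion
    n_de_cell_type: int = 4  # lncRNAs planted DA-vs-FP (plus their cis partners)
    n_de_timepoint: int = 4  # lncRNAs planted day16-vs-day60
    planted_lfc: float = 2.0
    read_length: int = 90
    spliced_reads: bool = False
    with_umi: bool = False

    def __post_init__(self) -> None:
        if self.n_lnc > self.n_coding:
            raise ValueError("need n_lnc <= n_coding (one host coding gene per lncRNA)")
        for f in ("n_chroms", "n_coding", "n_lnc", "read_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, n_exons: int,
                exon_len_range: tuple[int, int], intron_len_range: tuple[int, int]
                ) -> list[tuple[int, int]]:
    exons = []
    cursor = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len_range))
        exons.append((cursor, cursor + length))
        cursor += length
        if i < n_exons - 1:
            cursor += int(rng.integers(*intron_len_range))
    return exons


def simulate_annotation(cfg: SimConfig) -> tuple[GenomeAnnotation, dict]:
    """Build the planted annotation and its ground-truth relations.

    Coding genes are tiled along each chromosome with intergenic gaps of
    16-30 kb; each lncRNA is placed relative to its host coding gene per the
    cycled placement plan.  Exons are 1-3 per coding gene, 1-2 per lncRNA,
    all at least one read length long so read placement stays valid.
    """
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    truth_relations: dict[str, dict] = {}

    coding_per_chrom = [cfg.n_coding // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_coding % cfg.n_chroms):
        coding_per_chrom[i] += 1

    coding_models: list[GeneModel] = []
    next_gap: dict[str, int] = {}  # coding gene -> gap to the next coding span
    gidx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 10_000
        for _ in range(coding_per_chrom[c]):
            gidx += 1
            gid = f"PC{gidx:04d}"
            n_exons = int(rng.integers(1, 4))
            exons = _make_exons(rng, cursor, n_exons, (400, 1500), (500, 2500))
            gene = GeneModel(
                gene_id=gid,
                gene_name=f"CODING{gidx}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=exons[0][0],
                end=exons[-1][1],
                biotype="coding",
                exons=exons,
                raw_biotype="protein_coding",
            )
            coding_models.append(gene)
            gap = int(rng.integers(16_000, 30_000))
            next_gap[gid] = gap
            cursor = gene.end + gap
    genes.extend(coding_models)

    for i in range(cfg.n_lnc):
        host = coding_models[i]
        plan = cfg.lnc_plan[i % len(cfg.lnc_plan)]
        lid = f"LNC{i + 1:04d}"
        total_len = int(rng.integers(300, 2501))
        if plan == PLAN_ANTISENSE:
            strand = "-" if host.strand == "+" else "+"
            span = host.end - host.start
            length = min(total_len, span - 100)
            start = host.start + int(rng.integers(0, span - length))
            planted_gap = 0
        elif plan == PLAN_NEAR:
            strand = "+" if rng.random() < 0.5 else "-"
            planted_gap = int(rng.integers(1, 5001))
            start = host.end + planted_gap
            length = total_len
        elif plan == PLAN_FAR:
            strand = "+" if rng.random() < 0.5 else "-"
            hi = next_gap[host.gene_id] - total_len - 6000
            if hi < 6000:
                raise ValueError(f"intergenic gap after {host.gene_id} too short for 'far' plan")
            planted_gap = int(rng.integers(6000, hi + 1))
            start = host.end + planted_gap
            length = total_len
        else:
            raise ValueError(f"unknown placement plan {plan!r}")
        if length >= 2 * max(120, cfg.read_length + 30) and rng.random() < 0.4:
            split = int(rng.integers(cfg.read_length + 10, length - cfg.read_length - 10))
            intron = int(rng.integers(200, 800))
            exons = [(start, start + split), (start + split + intron, start + length + intron)]
        else:
            exons = [(start, start + length)]
        lnc = GeneModel(
            gene_id=lid,
            gene_name=f"LINC{i + 1}",
            chrom=host.chrom,
            strand=strand,
            start=exons[0][0],
            end=exons[-1][1],
            biotype="lncRNA",
            exons=exons,
            raw_biotype="lncRNA",
        )
        genes.append(lnc)
        truth_relations[lid] = {
            "plan": plan,
            "host": host.gene_id,
            "planted_gap_bp": planted_gap,
            "expected_class": "intergenic" if plan == PLAN_FAR else "intragenic",
        }

    return GenomeAnnotation(genes), {"relations": truth_relations}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _plant_fold_changes(cfg: SimConfig, ann: GenomeAnnotation, truth: dict,
                        rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Choose planted log2FCs: DA-vs-FP on lncRNAs and their cis hosts,
    day16-vs-day60 on a disjoint lncRNA set."""
    lnc_ids = sorted(g.gene_id for g in ann.by_biotype("lncRNA"))
    relations = truth["relations"]
    intragenic = [l for l in lnc_ids if relations[l]["expected_class"] == "intragenic"]
    others = [l for l in lnc_ids if l not in intragenic]
    ct_pool = intragenic + others  # prefer intragenic so cis pairs exist
    ct_genes = ct_pool[: cfg.n_de_cell_type]
    tp_pool = [l for l in lnc_ids if l not in ct_genes]
    tp_genes = tp_pool[: cfg.n_de_timepoint]

    lfc_ct: dict[str, float] = {}
    for lid in ct_genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc_ct[lid] = sign * cfg.planted_lfc
        # the cis coding partner co-moves -> positive cis correlation
        host = relations[lid]["host"]
        if relations[lid]["expected_class"] == "intragenic":
            lfc_ct[host] = sign * cfg.planted_lfc
    lfc_tp = {lid: (1.0 if rng.random() < 0.5 else -1.0) * cfg.planted_lfc for lid in tp_genes}
    return {"cell_type": lfc_ct, "timepoint": lfc_tp}


def _place_read(rng: np.random.Generator, gene: GeneModel, read_length: int,
                spliced: bool) -> list[tuple[int, int]]:
    if spliced and gene.mature_length > read_length:
        # uniform start in exon-union coordinates, mapped through junctions
        upos = int(rng.integers(0, gene.mature_length - read_length + 1))
        blocks = []
        remaining = read_length
        offset = 0
        for es, ee in gene.exons:
            elen = ee - es
            if upos >= offset + elen:
                offset += elen
                continue
            bstart = es + (upos - offset) if not blocks else es
            take = min(remaining, ee - bstart)
            blocks.append((bstart, bstart + take))
            remaining -= take
            offset += elen
            if remaining == 0:
                break
        return blocks
    candidates = [(s, e) for s, e in gene.exons if e - s >= read_length]
    if not candidates:
        candidates = [max(gene.exons, key=lambda iv: iv[1] - iv[0])]
        s, e = candidates[0]
        return [(s, e)]
    lens = np.array([e - s for s, e in candidates], dtype=float)
    idx = int(rng.choice(len(candidates), p=lens / lens.sum()))
    s, e = candidates[idx]
    start = s + int(rng.integers(0, e - s - read_length + 1))
    return [(start, start + read_length)]


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_reads(
    cfg: SimConfig, ann: GenomeAnnotation, truth: dict
) -> tuple[str, str, dict]:
    """Generate the SAM text, the cluster-map TSV text and extended truth.

    Per cell and gene the read count is NB(mu, dispersion) with
    mu = per_cell_gene_mean * abundance_g * 2^lfc for the cell's group;
    reads land uniformly within the gene's exon union on the gene's strand
    (forward chemistry), tagged CB with the cell barcode and NH:i:1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    gene_ids = sorted(ann.genes)
    abundance = {g: float(np.exp(rng.normal(0.0, 0.5))) for g in gene_ids}
    planted = _plant_fold_changes(cfg, ann, truth, rng)

    cmap_lines = ["barcode\tcluster\ttimepoint\tcell_type"]
    reads: list[tuple[str, int, int, str, str, str]] = []  # chrom,pos,flag,cigar,qname,barcode
    routing: dict[str, tuple[str, str]] = {}
    expected: dict[str, dict[str, int]] = {}
    counter = 0

    for spec in cfg.clusters:
        sample_id = f"{spec.cluster_id}:{spec.timepoint}"
        expected.setdefault(sample_id, {})
        for ci in range(spec.n_cells):
            barcode = f"{spec.cluster_id}-{ci:04d}"
            cmap_lines.append(
                f"{barcode}\t{spec.cluster_id}\t{spec.timepoint}\t{spec.cell_type}"
            )
            for gid in gene_ids:
                mu = cfg.per_cell_gene_mean * abundance[gid]
                lfc = 0.0
                if spec.cell_type == "DA":
                    lfc += planted["cell_type"].get(gid, 0.0)
                if spec.timepoint == "day60":
                    lfc += planted["timepoint"].get(gid, 0.0)
                mu *= 2.0**lfc
                r = 1.0 / cfg.dispersion
                n = int(rng.negative_binomial(r, r / (r + mu)))
                if n == 0:
                    continue
                gene = ann[gid]
                expected[sample_id][gid] = expected[sample_id].get(gid, 0) + n
                for _ in range(n):
                    counter += 1
                    qname = f"read{counter:08d}"
                    blocks = _place_read(rng, gene, cfg.read_length, cfg.spliced_reads)
                    flag = READ_FLAG_REVERSE if gene.strand == "-" else 0
                    tags = f"NH:i:1\tCB:Z:{barcode}"
                    if cfg.with_umi:
                        umi = "".join(rng.choice(list("ACGT"), size=8))
                        tags += f"\tUB:Z:{umi}"
                    reads.append(
                        (gene.chrom, blocks[0][0], flag, _blocks_to_cigar(blocks), qname, tags)
                    )
                    routing[qname] = (barcode, gid)

    chrom_ends = {}
    for g in ann.genes.values():
        chrom_ends[g.chrom] = max(chrom_ends.get(g.chrom, 0), g.end + 50_000)
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c}\tLN:{chrom_ends[c]}" for c in sorted(chrom_ends)]
    reads.sort(key=lambda r: (r[0], r[1], r[4]))
    body = [
        f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t*\t*\t{tags}"
        for chrom, pos, flag, cigar, qname, tags in reads
    ]
    sam_text = "\n".join(header + body) + "\n"
    cmap_text = "\n".join(cmap_lines) + "\n"

    truth = dict(truth)
    truth["planted_lfc"] = planted
    truth["read_routing"] = routing
    truth["expected_counts"] = expected
    truth["abundance"] = abundance
    return sam_text, cmap_text, truth


def simulate_dataset(cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Emit coding.gtf, lncrna.gtf, reads.sam, clusters.tsv, truth.json."""
    os.makedirs(outdir, exist_ok=True)
    ann, truth = simulate_annotation(cfg)
    sam_text, cmap_text, truth = simulate_reads(cfg, ann, truth)
    paths = {
        "coding_gtf": os.path.join(outdir, "coding.gtf"),
        "lnc_gtf": os.path.join(outdir, "lncrna.gtf"),
        "sam": os.path.join(outdir, "reads.sam"),
        "clusters": os.path.join(outdir, "clusters.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_gtf(ann, paths["coding_gtf"], biotypes={"coding"})
    write_gtf(ann, paths["lnc_gtf"], biotypes={"lncRNA"})
    with open(paths["sam"], "w") as fh:
        fh.write(sam_text)
    with open(paths["clusters"], "w") as fh:
        fh.write(cmap_text)
    truth_out = dict(truth)
    truth_out["config"] = asdict(cfg)
    with open(paths["truth"], "w") as fh:
        json.dump(truth_out, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# matrix-level NB simulation (for the DE stage in isolation)
# ---------------------------------------------------------------------------

def simulate_nb_matrix(
    n_genes: int,
    n_per_group: int,
    dispersion: float,
    planted_lfc: dict[int, float] | None = None,
    mean_range: tuple[float, float] = (20.0, 200.0),
    depth_factors: np.ndarray | None = None,
    seed: int = 0,
    group_labels: tuple[str, str] = ("FP", "DA"),
) -> tuple[CountMatrix, dict]:
    """Pseudobulk-level NB count matrix with planted per-gene log2FCs.

    Two groups of ``n_per_group`` samples; baseline means are log-uniform in
    ``mean_range``; group-2 means are scaled by 2^lfc for planted genes.
    ``depth_factors`` optionally scales per-sample sequencing depth.
    Returns the CountMatrix (samples labeled as cell types at one shared
    timepoint) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    planted_lfc = planted_lfc or {}
    means = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))
    lfc = np.zeros(n_genes)
    for idx, value in planted_lfc.items():
        lfc[idx] = value
    n_samples = 2 * n_per_group
    if depth_factors is None:
        depth_factors = np.ones(n_samples)
    depth_factors = np.asarray(depth_factors, dtype=float)
    mu = np.tile(means[:, None], (1, n_samples)).astype(float)
    mu[:, n_per_group:] *= 2.0 ** lfc[:, None]
    mu *= depth_factors[None, :]
    r = 1.0 / max(dispersion, 1e-12)
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    samples = [
        SampleInfo(
            sample_id=f"{group_labels[0]}_{j:02d}:day16",
            cluster=f"{group_labels[0]}_{j:02d}",
            timepoint="day16",
            cell_type=group_labels[0],
        )
        for j in range(n_per_group)
    ] + [
        SampleInfo(
            sample_id=f"{group_labels[1]}_{j:02d}:day16",
            cluster=f"{group_labels[1]}_{j:02d}",
            timepoint="day16",
            cell_type=group_labels[1],
        )
        for j in range(n_per_group)
    ]
    matrix = CountMatrix(gene_ids, samples, counts)
    truth = {
        "means": means,
        "lfc": {gene_ids[i]: v for i, v in planted_lfc.items()},
        "dispersion": dispersion,
        "alt_group": group_labels[1],
    }
    return matrix, truth
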