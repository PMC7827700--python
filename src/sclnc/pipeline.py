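"""End-to-end orchestration: count -> differential expression -> context.

``run_pipeline`` executes the full chain on one input set and writes every
artifact plus a manifest with checksums; rerunning with identical inputs and
seed is byte-identical for the deterministic stages (all of them — the only
randomness in the package lives in the simulator).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import pysam
import yaml

from . import annotation as ann_mod
from . import context as ctx_mod
from . import diffexp, quantify, reads

log = logging.getLogger(__name__)


class UserInputError(ValueError):
    """Bad paths or parameters; maps to CLI exit code 2."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name. Maps to CLI exit code 3."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Parameter defaults are the profiling conventions the tool implements:
    forward-strand counting, a 5 kb cis window, padj < 0.01 significance and
    a baseMean >= 1 expression filter.
    """

    bam: str
    clusters: str
    outdir: str
    gtf: str | None = None  # coding annotation
    lnc_gtf: str | None = None  # lncRNA annotation
    strandness: str = "forward"
    barcode_tag: str = "CB"
    window: int = 5000
    alpha: float = 0.01
    min_base_mean: float = 1.0
    seed: int = 0
    lnc_only: bool = False  # count against the lncRNA annotation alone
    umi_dedup: bool = False
    min_mapq: int = 0
    pseudo_reference: bool = False
    log_level: str = "INFO"

    def annotation_paths(self) -> list[str]:
        if self.lnc_only:
            paths = [self.lnc_gtf]
        else:
            paths = [self.gtf, self.lnc_gtf]
        out = [p for p in paths if p]
        if not out:
            raise UserInputError("no annotation GTF provided")
        return out

    def validate(self) -> None:
        for name in ("bam", "clusters"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise UserInputError(f"{name} file not found: {path}")
        for path in self.annotation_paths():
            if not os.path.exists(path):
                raise UserInputError(f"annotation file not found: {path}")
        if self.strandness not in ("forward", "reverse", "unstranded"):
            raise UserInputError(f"unknown strandness {self.strandness!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _pick_levels(values: set[str], contrast: str) -> tuple[str, str] | None:
    """Default contrast levels: DA vs FP for cell type (positive log2FC =
    up in DA); day16 vs day60 for timepoints; else the lexicographic
    extremes of a two-level factor."""
    if len(values) < 2:
        return None
    if contrast == "cell_type" and values >= {"DA", "FP"}:
        return ("FP", "DA")
    if contrast == "timepoint" and values >= {"day16", "day60"}:
        return ("day16", "day60")
    ordered = sorted(values)
    return (ordered[0], ordered[-1])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute count -> DE (both contrasts) -> context -> summaries.

    Returns the manifest (also written to ``outdir/manifest.json``): one
    entry per artifact with its sha256.  On failure, artifacts written so
    far are moved to ``outdir/failed/`` and a :class:`PipelineError` naming
    the stage is raised.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, filename: str) -> str:
        path = os.path.join(cfg.outdir, filename)
        artifacts[name] = path
        return path

    try:
        with open(emit("config", "config.resolved.yaml"), "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

        stage = "annotation"
        annotation = ann_mod.parse_gtf(cfg.annotation_paths())
        log.info("loaded %d genes (%d coding, %d lncRNA)", len(annotation),
                 len(annotation.by_biotype("coding")), len(annotation.by_biotype("lncRNA")))

        stage = "count"
        cmap = reads.load_cluster_map(cfg.clusters)
        with pysam.AlignmentFile(cfg.bam, check_sq=False) as fh:
            ann_mod.check_chromosome_dialects(annotation, set(fh.references or ()))
        summary = reads.PartitionSummary()
        stream = reads.stream_alignments(
            cfg.bam, barcode_tag=cfg.barcode_tag, min_mapq=cfg.min_mapq, summary=summary
        )
        partitions, summary = reads.partition_by_cluster(stream, cmap, summary=summary)
        matrix, tallies = quantify.count_all_partitions(
            partitions, annotation, cmap.samples(),
            strandness=cfg.strandness, umi_dedup=cfg.umi_dedup,
        )
        matrix.write_tsv(emit("counts", "counts.tsv"))
        matrix.sample_metadata().to_csv(emit("samples", "samples.tsv"), sep="\t")
        tallies.to_csv(emit("assignment_tallies", "assignment_tallies.tsv"), sep="\t")
        summary.to_frame().to_csv(
            emit("partition_summary", "partition_summary.tsv"), sep="\t", index=False
        )

        stage = "normalize"
        s = diffexp.size_factors_median_ratios(
            matrix.counts, pseudo_reference=cfg.pseudo_reference
        )
        norm = diffexp.normalized_counts(matrix.counts, s)
        bm_all = pd.Series(norm.mean(axis=1), index=matrix.gene_ids)

        stage = "diffexp"
        meta = matrix.sample_metadata()
        de_tables: dict[str, diffexp.DETable] = {}
        for contrast in ("cell_type", "timepoint"):
            levels = _pick_levels(set(meta[contrast]), contrast)
            if levels is None:
                log.warning("contrast %s has <2 levels; skipped", contrast)
                continue
            de = diffexp.run_de(
                matrix, contrast=contrast, levels=levels,
                alpha=cfg.alpha, min_base_mean=cfg.min_base_mean,
                pseudo_reference=cfg.pseudo_reference,
            )
            de.write_tsv(emit(f"de_{contrast}", f"de_{contrast}.tsv"))
            de_tables[contrast] = de

        stage = "context"
        pair_table = ctx_mod.build_cis_pairs(annotation, window=cfg.window)
        pair_table.to_csv(emit("context", "context.tsv"), sep="\t", index=False)
        cis_r = float("nan")
        n_pairs = 0
        if "cell_type" in de_tables:
            pairs_lfc = ctx_mod.attach_fold_changes(
                pair_table, de_tables["cell_type"], significant_only=True, require="both"
            )
            cis_r, n_pairs, per_pair = ctx_mod.cis_correlation(pairs_lfc)
            per_pair.to_csv(emit("cis_pairs", "cis_pairs.tsv"), sep="\t", index=False)

        expressed = ctx_mod.expressed_genes(bm_all, annotation, threshold=cfg.min_base_mean)
        n_sense, n_antisense = ctx_mod.strand_tally(expressed["lncRNA"])
        hist, edges = ctx_mod.length_distribution(expressed["lncRNA"])
        pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist}
        ).to_csv(emit("length_histogram", "length_histogram.tsv"), sep="\t", index=False)

        dist = ctx_mod.distance_matrix(norm)
        pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids).to_csv(
            emit("distance_matrix", "distance_matrix.tsv"), sep="\t"
        )
        coords, explained = ctx_mod.pca_embedding(norm, n_components=2)
        pca_df = pd.DataFrame(
            coords, index=matrix.sample_ids,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        )
        pca_df["explained_variance"] = list(explained) + [np.nan] * (
            len(pca_df) - len(explained)
        )
        pca_df.to_csv(emit("pca", "pca.tsv"), sep="\t")
        for contrast, de in de_tables.items():
            ctx_mod.ma_table(de).to_csv(
                emit(f"ma_{contrast}", f"ma_{contrast}.tsv"), sep="\t", index=False
            )

        stage = "summary"
        class_counts = pair_table["class"].value_counts().to_dict() if len(pair_table) else {}
        run_summary = {
            "n_genes": len(annotation),
            "n_lncRNA_annotated": len(annotation.by_biotype("lncRNA")),
            "n_expressed_lncRNA": len(expressed["lncRNA"]),
            "n_expressed_coding": len(expressed["coding"]),
            "n_sense": n_sense,
            "n_antisense": n_antisense,
            "intragenic": int(class_counts.get("intragenic", 0)),
            "intergenic": int(class_counts.get("intergenic", 0)),
            "cis_pearson_r": None if np.isnan(cis_r) else cis_r,
            "cis_n_pairs": n_pairs,
            "reads_assigned_to_samples": summary.n_assigned,
            "reads_dropped": dict(summary.dropped),
            "n_significant": {
                c: int(t.table["significant"].sum()) for c, t in de_tables.items()
            },
        }
        with open(emit("summary", "summary.json"), "w") as fh:
            json.dump(run_summary, fh, indent=1, sort_keys=True)

        stage = "manifest"
        manifest = {
            "artifacts": {
                name: {"path": os.path.basename(path), "sha256": _sha256(path)}
                for name, path in sorted(artifacts.items())
            },
            "parameters": asdict(cfg),
        }
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest

    except UserInputError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        failed_dir = os.path.join(cfg.outdir, "failed")
        os.makedirs(failed_dir, exist_ok=True)
        for path in artifacts.values():
            if os.path.exists(path):
                shutil.move(path, os.path.join(failed_dir, os.path.basename(path)))
        raise PipelineError(stage, exc) from exc
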