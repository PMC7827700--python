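# Methods

This note documents the models, conventions and numerical choices behind
`sclnc`, and what the synthetic-data tests do and do not establish about
behavior on real data.

## Coordinates and annotation

GTF input/output is 1-based inclusive; everything in memory is 0-based
half-open, and public accessors (`span_start`, `exons_1based`) convert
back. Exon lists are merged on construction, so a gene's *mature length* is
simply the total size of its exon union — the quantity the strand-specific
counter actually sees. Span length (gene end − start) is available as an
alternative for length summaries. Biotypes are collapsed from the raw GTF
value: `protein_coding` → coding; `lncRNA` and the legacy `antisense` /
`lincRNA` → lncRNA; everything else → other. "Other" genes stay in the
interval index — they compete for read assignment like any gene — but are
excluded from lncRNA/coding reports. Chromosome-name dialects ("chr1" vs
"1") are never silently normalized; a disjoint annotation/alignment
chromosome set triggers a warning, because guessing the dialect is how
reads silently vanish.

## Read handling

Reference blocks are derived from the CIGAR: M/=/X and D extend the current
block, N closes it, I/S/H/P consume no reference. Unmapped, secondary and
supplementary records are skipped and tallied; records with NH > 1 are
dropped as multimapped (the default of standard exon-union counters);
barcode matching is exact, with no whitelist or error correction. Counting
is per *read* by default — the upstream protocol this mirrors counts
cluster-level BAMs directly — with an optional UMI mode that collapses
duplicate (gene, barcode, UMI) triples after assignment. No MAPQ filter is
applied by default (`--min-mapq` exposes one). Every drop is tallied by
reason and the invariant `assigned + dropped = total` is enforced by test.

## Assignment

A read's candidate genes are those whose exon union overlaps ≥1 bp of any
block (minimum overlap configurable) and whose strand is compatible:
`forward` (default, matching 3' single-cell chemistry as processed here)
requires gene strand == read strand. One candidate → assigned; several →
ambiguous (discarded, never fractionally split); none, but an
opposite-strand exon overlap exists → strand_mismatch; else no_feature. By
default coding and lncRNA annotations are counted *competitively* in one
run, so a sense-strand coding read overlapping an antisense lncRNA cannot
be misattributed; `--lnc-only` restricts the annotation to lncRNAs alone
for compatibility with single-annotation workflows. Both modes are tested.

## Differential expression

The model is the standard bulk NB GLM applied to pseudobulk samples
(cluster × timepoint), which are the statistical replicates; fewer than two
replicates per level warns but does not abort.

- **Size factors** are median-of-ratios: s_j = median over reference genes
  of counts[g,j] / geomean_g. Reference genes must be positive in every
  sample; `pseudo_reference=True` switches the geometric mean to positive
  entries only, for sparse matrices. Only *ratios* of size factors are
  identified — scaling one of n columns by c multiplies its factor by
  c^((n−1)/n) and the others by c^(−1/n), preserving all ratios — and all
  downstream quantities depend on the factors only through ratios plus one
  global scale.
- **Dispersion** α_g (variance μ + αμ²) is estimated per gene by
  alternating the IRLS mean fit with a bounded 1-D maximization of the
  Cox–Reid adjusted profile likelihood (ℓ(α) − ½ log det XᵀWX) on the log-α
  scale, to convergence 1e-6 or 20 alternations, floored at 1e-8. The CR
  term charges the likelihood for the fitted mean parameters; without it
  the estimator is biased low at pseudobulk sample sizes and the Wald test
  becomes anticonservative. A method-of-moments fallback covers ML
  failures.
- **Wald test.** Per gene, the NB GLM (log link, offset log s_j, design =
  intercept + contrast indicator, optional additive covariate) is fit by
  IRLS with the linear predictor clipped to ±30 so all-zero groups stay
  finite; log2FC = β/ln 2 and its SE come from the observed Fisher
  information; two-sided normal p-values; BH step-up adjustment;
  significance padj < α (default 0.01). Genes below baseMean 1 (mean
  normalized count) are excluded before testing; the threshold is a flag
  and the ≥ (not >) convention is deliberate.
- **Deliberate simplifications:** no empirical-Bayes dispersion shrinkage,
  no LFC shrinkage, no independent filtering beyond the baseMean rule, no
  outlier replacement. The practical consequence: at 10–20 pseudobulks
  per group, gene-wise dispersions are noisy, and the realized
  false-discovery proportion in the extreme tail runs ~2× the BH nominal
  level — a documented cost of keeping the inference transparent. The two
  contrasts (cell type; day 16 vs day 60) are run as separate one-factor
  analyses; day-30 samples inform the cell-type contrast but are excluded
  from the timepoint contrast.

## Genomic context and cis pairs

The 5 kb rule is measured between *gene spans*: gap = 0 on overlap, else
the bp separation; a lncRNA is intragenic iff gap ≤ 5000 (boundary
inclusive). Nearest-coding-gene search uses sorted spans with a
prefix-max-end bound so overlapping spans are handled exactly; ties on gap
break by lexicographically smallest gene id, making classification
deterministic, and the result is property-tested against an exhaustive
scan. The relation field (overlapping_sense / overlapping_antisense /
upstream / downstream, upstream meaning 5' of the coding gene in its own
orientation) preserves the information the binary class discards. Cis
pairs take both log2 fold changes from one shared contrast; pairs where
either partner was untested are dropped and tallied, and the significance
filter (padj < α) defaults to requiring *both* partners (configurable to
either alone). Pearson r is reported with the pair count and the
sign-concordance fraction; fewer than 3 pairs or zero variance yields an
explicit NaN.

Distance matrices and PCA operate on log2(normalized + 1) — the +1
pseudocount is a documented stand-in for a variance-stabilizing transform.
PCA centers genes, uses SVD, and fixes each component's sign so its
largest-magnitude gene loading is positive, making embeddings
deterministic.

## The simulator

`SimConfig` defaults emulate the target study at desk scale: DA and FP
populations at days 16/30/60 (one cluster each, 40 cells), 30 coding genes
tiled with 16–30 kb gaps over 2 chromosomes, 18 lncRNAs cycled through
three placements — antisense inside a coding span, 1–5000 bp away
(intragenic), ≥6000 bp away (intergenic) — with mature lengths 300–2500 bp,
matching the length range the method targets. Per cell and gene, read
counts are NB with per-cell mean 0.5 × a lognormal gene abundance and
dispersion 0.05; planted log2 fold changes (default magnitude 2, random
sign — both DA- and FP-enriched lncRNAs exist, as in the biology) scale the
mean for the affected group, and each planted intragenic lncRNA's host
coding gene co-moves so cis pairs are genuinely correlated. Reads are 90 bp
on the gene's strand (forward chemistry), placed uniformly within single
exons by default (an option plants junction-spanning reads with N gaps),
tagged CB/NH:i:1, emitted as coordinate-sorted SAM text. Identical seeds
give byte-identical files.

`simulate_nb_matrix` generates pseudobulk-level NB count matrices directly
(baseline means log-uniform 20–200, two groups, planted per-gene LFCs) for
testing the DE stage in isolation at chosen replication.

What passing on this synthetic data does *not* show: robustness to barcode
errors, multimapping structure, intronic/ambient reads, non-NB
overdispersion, batch effects, or annotation incompleteness — none of
which the generator emulates. It does establish algorithmic correctness
(oracle-equivalent counting, exact accounting, deterministic outputs) and
statistical calibration under the model's own assumptions.

## Problem sizes

Test and acceptance runs use 10–60 genes and ~7–25k reads for end-to-end
checks, and 500-gene matrices with 10–20 pseudobulks per group for
inference calibration — sizes at which every check completes in seconds
while keeping ≥50 planted effects for stable sensitivity/FDP estimates.
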