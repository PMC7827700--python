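"""Negative-binomial differential expression for pseudobulk count matrices.

The model is the classic bulk RNA-seq one: counts K_gj ~ NB(mu_gj, alpha_g)
with variance mu + alpha*mu^2, mean mu_gj = s_j * q_gj, log q_gj = x_j' beta_g,
where s_j are median-of-ratios size factors and the design holds an intercept
plus a two-level contrast indicator (optionally an additive covariate).
Per-gene dispersion alpha_g is estimated by maximizing the Cox-Reid adjusted
profile likelihood, alternating with the IRLS mean fit; the contrast
coefficient is tested with a Wald statistic against the normal reference and
adjusted with Benjamini-Hochberg.

Deliberate simplifications relative to the full DESeq2 procedure: no
empirical-Bayes dispersion shrinkage, no LFC shrinkage, no independent
filtering beyond the baseMean threshold, no outlier replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .quantify import CountMatrix

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors_median_ratios(
    counts: np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over reference genes g of
    counts[g, j] / geomean_j'(counts[g, j']).  Reference genes are those with
    positive counts in every sample; with ``pseudo_reference`` the geometric
    mean is instead taken over the positive entries of each row so sparse
    matrices without an all-positive gene remain normalizable.

    Parameters
    ----------
    counts : array (genes, samples) of non-negative counts
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_positive = np.all(counts > 0, axis=1)
    if not pseudo_reference:
        if not np.any(all_positive):
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "pseudo_reference=True (CLI: --pseudo-reference)"
            )
        log_geomean = np.full(counts.shape[0], -np.inf)
        log_geomean[all_positive] = logc[all_positive].mean(axis=1)
    else:
        npos = (counts > 0).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            log_geomean = np.where(
                npos > 0, np.where(logc == -np.inf, 0.0, logc).sum(axis=1) / np.maximum(npos, 1), -np.inf
            )
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        with np.errstate(invalid="ignore"):
            ratios = logc[:, j] - log_geomean
        usable = np.isfinite(ratios)
        if not np.any(usable):
            raise ValueError(f"sample {j}: no usable reference gene for size factor")
        factors[j] = np.exp(np.median(ratios[usable]))
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factors must be finite and positive")
    return factors


def normalized_counts(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """counts[g, j] / s_j; the log2(x + 1) transform is applied downstream."""
    counts = np.asarray(counts, dtype=float)
    return counts / np.asarray(size_factors, dtype=float)[np.newaxis, :]


def base_means(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Per-gene mean of size-factor-normalized counts across samples."""
    return normalized_counts(counts, size_factors).mean(axis=1)


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.clip(mu, 1e-10, None)
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB GLM with log link by iteratively reweighted least squares.

    Returns (beta, fisher_information_matrix, converged).  The linear
    predictor is clipped to +/-30 so groups with all-zero counts stay finite
    (their coefficient is then reported with a huge standard error rather
    than crashing the fit).
    """
    n, p = X.shape
    # start from a least-squares fit on the shifted log scale
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        info = xtw @ X + np.eye(p) * 1e-10
        try:
            beta_new = np.linalg.solve(info, xtw @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X + np.eye(p) * 1e-10
    return beta, info, converged


def _cr_adjusted_loglik(
    alpha: float, y: np.ndarray, mu: np.ndarray, X: np.ndarray
) -> float:
    """Cox-Reid adjusted profile log-likelihood of the dispersion.

    The -0.5*logdet(X'WX) term charges the likelihood for the fitted mean
    parameters; without it gene-wise ML dispersions at pseudobulk sample
    sizes are biased low and the downstream Wald test is anticonservative.
    """
    w = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X + np.eye(X.shape[1]) * 1e-10)
    return _nb_loglik(y, mu, alpha) - 0.5 * (logdet if sign > 0 else 0.0)


def _mom_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments fallback: alpha = (var - mean) / mean^2 on residuals."""
    m = float(np.mean(mu))
    if m <= 0:
        return DISPERSION_FLOOR
    resid_var = float(np.mean((y - mu) ** 2))
    return max(DISPERSION_FLOOR, (resid_var - m) / m**2)


def estimate_dispersion_single(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    max_outer: int = 20,
    outer_tol: float = 1e-6,
) -> float:
    """Gene-wise dispersion: alternate IRLS mean fit and 1-D CR-ML in alpha."""
    y = np.asarray(y, dtype=float)
    alpha = 0.1
    for _ in range(max_outer):
        beta, _, _ = _irls_fit(y, X, offset, alpha)
        mu = np.exp(np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP))
        try:
            res = optimize.minimize_scalar(
                lambda la: -_cr_adjusted_loglik(np.exp(la), y, mu, X),
                bounds=(np.log(DISPERSION_FLOOR), np.log(50.0)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            new_alpha = float(np.exp(res.x))
            if not np.isfinite(res.fun):
                raise FloatingPointError("non-finite likelihood")
        except (FloatingPointError, ValueError):
            log.warning("dispersion ML failed; using method-of-moments fallback")
            return _mom_dispersion(y, mu)
        if abs(new_alpha - alpha) < outer_tol:
            return max(new_alpha, DISPERSION_FLOOR)
        alpha = new_alpha
    return max(alpha, DISPERSION_FLOOR)


def estimate_dispersion(
    counts: np.ndarray, size_factors: np.ndarray, design: np.ndarray
) -> np.ndarray:
    """Per-gene NB dispersion estimates for a genes x samples count matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs >=2 samples")
    offset = np.log(np.asarray(size_factors, dtype=float))
    return np.array(
        [estimate_dispersion_single(row, design, offset) for row in counts]
    )


# ---------------------------------------------------------------------------
# Wald contrast
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene Wald results for one two-level contrast.

    ``table`` columns: gene_id, baseMean, log2FoldChange, lfcSE, stat,
    pvalue, padj, significant, converged.  log2FoldChange is
    level[1] vs level[0] (positive = higher in level[1]).
    """

    table: pd.DataFrame
    contrast: str
    levels: tuple[str, str]
    alpha: float = 0.01
    min_base_mean: float = 1.0
    n_excluded_low_expression: int = 0

    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene_id"].tolist()

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# contrast={self.contrast} levels={self.levels[0]},{self.levels[1]} "
                f"alpha={self.alpha} min_base_mean={self.min_base_mean}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str) -> "DETable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing DETable metadata header line")
            meta = dict(item.split("=", 1) for item in header[1:].split())
            table = pd.read_csv(fh, sep="\t")
        levels = tuple(meta["levels"].split(","))
        return cls(
            table=table,
            contrast=meta["contrast"],
            levels=(levels[0], levels[1]),
            alpha=float(meta["alpha"]),
            min_base_mean=float(meta["min_base_mean"]),
        )


def nb_wald_contrast(
    counts: np.ndarray,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    design: np.ndarray,
    gene_ids: list[str],
    contrast_col: int = 1,
) -> pd.DataFrame:
    """Wald test of one design coefficient for every gene.

    Fits the NB GLM per gene at its fixed dispersion, reads the contrast
    coefficient and its standard error off the observed Fisher information,
    and returns two-sided normal p-values.  Genes whose IRLS fit does not
    converge are flagged and carry undefined p.
    """
    counts = np.asarray(counts, dtype=float)
    offset = np.log(np.asarray(size_factors, dtype=float))
    bm = base_means(counts, size_factors)
    rows = []
    for i, gid in enumerate(gene_ids):
        y = counts[i]
        if np.all(y == 0):
            rows.append((gid, 0.0, np.nan, np.nan, np.nan, np.nan, False))
            continue
        beta, info, converged = _irls_fit(y, design, offset, dispersions[i])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            converged = False
            cov = np.full_like(info, np.nan)
        l2fc = beta[contrast_col] / _LN2
        se = np.sqrt(max(cov[contrast_col, contrast_col], 0.0)) / _LN2
        if converged and np.isfinite(se) and se > 0:
            wald = l2fc / se
            pval = 2.0 * stats.norm.sf(abs(wald))
        else:
            wald, pval = np.nan, np.nan
        rows.append((gid, bm[i], l2fc, se, wald, pval, converged))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "converged"],
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{k>=i} (m/k) * p_(k), capped at 1 and mapped back to the
    input order.  NaN entries are excluded from m and stay NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    pd_ = p[defined]
    if np.any((pd_ < 0) | (pd_ > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pd_.size
    if m == 0:
        return out
    order = np.argsort(pd_, kind="mergesort")
    ranked = pd_[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adj, 1.0)
    out[defined] = result
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_design_matrix(
    metadata: pd.DataFrame,
    contrast: str,
    levels: tuple[str, str],
    covariate: str | None = None,
) -> np.ndarray:
    """Intercept + contrast indicator (+ covariate dummies, first level dropped)."""
    indicator = (metadata[contrast] == levels[1]).to_numpy(dtype=float)
    cols = [np.ones(len(metadata)), indicator]
    if covariate is not None:
        values = sorted(metadata[covariate].unique())
        for v in values[1:]:
            cols.append((metadata[covariate] == v).to_numpy(dtype=float))
    return np.column_stack(cols)


def run_de(
    matrix: CountMatrix,
    contrast: str,
    levels: tuple[str, str] | None = None,
    covariate: str | None = None,
    alpha: float = 0.01,
    min_base_mean: float = 1.0,
    metadata: pd.DataFrame | None = None,
    pseudo_reference: bool = False,
) -> DETable:
    """Full pipeline for one contrast: size factors -> dispersion -> Wald -> BH.

    ``contrast`` names a column of the sample metadata (``cell_type`` or
    ``timepoint``); samples outside the two contrast levels are excluded.
    Genes below ``min_base_mean`` normalized mean expression are excluded
    before testing; significance is padj < alpha.
    """
    meta = metadata if metadata is not None else matrix.sample_metadata()
    if contrast not in meta.columns:
        raise ValueError(f"contrast {contrast!r} is not a sample metadata column")
    observed = sorted(meta[contrast].unique())
    if levels is None:
        if len(observed) != 2:
            raise ValueError(
                f"contrast {contrast!r} has levels {observed}; pass levels=(ref, alt)"
            )
        levels = (observed[0], observed[1])
    keep = meta[contrast].isin(levels).to_numpy()
    meta = meta.loc[keep]
    counts = matrix.counts[:, keep]
    for level in levels:
        n = int((meta[contrast] == level).sum())
        if n == 0:
            raise ValueError(f"contrast level {level!r} has no samples")
        if n < 2:
            log.warning("contrast level %r has a single sample; no replication", level)

    s = size_factors_median_ratios(counts, pseudo_reference=pseudo_reference)
    bm = base_means(counts, s)
    tested = bm >= min_base_mean
    n_excluded = int((~tested).sum())

    design = build_design_matrix(meta, contrast, levels, covariate)
    sub = counts[tested, :]
    gene_ids = [g for g, t in zip(matrix.gene_ids, tested) if t]
    dispersions = estimate_dispersion(sub, s, design)
    table = nb_wald_contrast(sub, s, dispersions, design, gene_ids)
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    table["significant"] = table["padj"] < alpha
    table["significant"] = table["significant"].fillna(False)
    table = table[
        ["gene_id", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj",
         "significant", "converged"]
    ]
    return DETable(
        table=table.reset_index(drop=True),
        contrast=contrast,
        levels=levels,
        alpha=alpha,
        min_base_mean=min_base_mean,
        n_excluded_low_expression=n_excluded,
    )
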