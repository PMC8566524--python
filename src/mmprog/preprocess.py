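"""Cell/gene quality control, depth normalization, variable-gene selection,
and covariate-regressed scaling.

Conventions
-----------
* QC inequalities are strict on the removal side: a cell is removed when it
  has *fewer than* ``min_genes`` detected genes, *fewer than* ``min_umi``
  transcripts, or *more than* ``max_pct_mito`` percent mitochondrial UMIs.
  A cell sitting exactly on a threshold is kept.
* Normalization is natural-log: ``ln(count / cell_total * scale + 1)`` with
  ``scale = 10000``; downstream log fold changes are therefore in ln units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ExpressionMatrix

logger = logging.getLogger("mmprog")


@dataclass
class QcThresholds:
    min_genes: int = 500
    min_umi: int = 1000
    max_pct_mito: float = 15.0
    #: a gene must be detected in at least this fraction of the average
    #: number of cells per sample (rounded up, floored at one cell)
    min_gene_cell_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("QC thresholds must be positive")
        if not (0 < self.max_pct_mito <= 100):
            raise ValueError("max_pct_mito must lie in (0, 100]")
        if self.min_gene_cell_fraction <= 0:
            raise ValueError("min_gene_cell_fraction must be positive")


def cell_qc_metrics(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total UMIs, percent mitochondrial UMIs."""
    counts = matrix.counts.tocsc()
    n_genes = counts.getnnz(axis=0)
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    mito = annotation.set_index("gene_id")["is_mito"].reindex(matrix.gene_ids)
    mito_mask = mito.fillna(False).to_numpy(dtype=bool)
    mito_umi = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"cell_id": matrix.cell_ids, "n_genes": n_genes,
         "n_umi": n_umi.astype(np.int64), "pct_mito": pct}
    )


def qc_filter_cells(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells; return the filtered matrix and a QC report.

    The report carries every input cell with its three metrics, a ``kept``
    flag, and the comma-joined list of failed rules for removed cells.
    """
    thresholds = thresholds or QcThresholds()
    report = cell_qc_metrics(matrix, annotation)
    fail_genes = report["n_genes"] < thresholds.min_genes
    fail_umi = report["n_umi"] < thresholds.min_umi
    fail_mito = report["pct_mito"] > thresholds.max_pct_mito
    reasons = []
    for fg, fu, fm in zip(fail_genes, fail_umi, fail_mito):
        r = [name for flag, name in
             ((fg, "min_genes"), (fu, "min_umi"), (fm, "max_pct_mito")) if flag]
        reasons.append(",".join(r))
    report["kept"] = ~(fail_genes | fail_umi | fail_mito)
    report["reasons"] = reasons
    kept = report.loc[report["kept"], "cell_id"].to_numpy()
    if len(kept) == 0:
        raise ValueError("all cells removed by QC")
    logger.info("preprocess.qc_filter_cells: kept %d / %d cells",
                len(kept), matrix.n_cells)
    return matrix.subset(cells=kept), report


def filter_genes(
    matrix: ExpressionMatrix,
    sample_labels: pd.Series | np.ndarray,
    thresholds: QcThresholds | None = None,
) -> ExpressionMatrix:
    """Drop lowly expressed genes.

    A gene is kept iff it is detected (count > 0) in at least
    ``ceil(min_gene_cell_fraction * n_cells / n_samples)`` cells, with the
    cutoff floored at one cell.
    """
    thresholds = thresholds or QcThresholds()
    labels = np.asarray(sample_labels)
    if len(labels) != matrix.n_cells:
        raise ValueError("sample_labels length must equal number of cells")
    n_samples = len(pd.unique(labels))
    avg_cells = matrix.n_cells / n_samples
    cutoff = max(1, int(np.ceil(thresholds.min_gene_cell_fraction * avg_cells)))
    detected = matrix.counts.getnnz(axis=1)
    keep = detected >= cutoff
    logger.info("preprocess.filter_genes: cutoff %d cells, kept %d / %d genes",
                cutoff, int(keep.sum()), matrix.n_genes)
    return matrix.subset(genes=matrix.gene_ids[keep])


def lognormalize(matrix: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Populate the normalized layer: ``ln(count / cell_total * scale + 1)``.

    Zero counts map to exactly 0, so the layer keeps the counts' sparsity.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = matrix.cell_ids[int(np.argmin(totals))]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    norm = matrix.counts.tocsc().astype(np.float64)
    # scale each column by scale/total, then log1p the stored values
    norm = norm @ sp.diags(scale / totals)
    norm.data = np.log1p(norm.data)
    matrix.normalized = norm.tocsr()
    return matrix


def _loess_trend(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Local quadratic regression with tricube weights (loess), fitted at
    every x. O(n^2) in genes, fine at the few-thousand-gene scale."""
    n = len(x)
    k = max(5, int(np.ceil(span * n)))
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    for pos in range(n):
        d = np.abs(xs - xs[pos])
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - np.minimum(d[idx] / max(h, 1e-12), 1) ** 3) ** 3
        X = np.column_stack([np.ones(k), xs[idx] - xs[pos],
                             (xs[idx] - xs[pos]) ** 2])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ ys[idx], rcond=None)
        fitted_sorted[pos] = beta[0]
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def select_hvg(matrix: ExpressionMatrix, n: int = 3000, span: float = 0.3) -> np.ndarray:
    """Rank genes by variance-stabilized standardized variance; return the top n.

    The expected standard deviation of each gene is read off a local
    polynomial fit of log10(variance) on log10(mean) of the raw counts;
    counts standardized by that sd are clipped at sqrt(n_cells) before the
    ranking variance is computed.
    """
    if n > matrix.n_genes:
        raise ValueError(f"requested {n} variable genes but matrix has {matrix.n_genes}")
    counts = matrix.counts
    n_cells = matrix.n_cells
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = counts.copy()
    sq.data = sq.data.astype(np.float64) ** 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = var * n_cells / max(n_cells - 1, 1)

    est_var = np.zeros(matrix.n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 5:
        trend = _loess_trend(np.log10(mean[ok]), np.log10(var[ok]), span=span)
        exp_sd = np.sqrt(10.0**trend)
        clip = np.sqrt(n_cells)
        # standardized variance computed sparsely: only nonzero entries differ
        # from the standardized zero value -mean/sd
        idx_ok = np.flatnonzero(ok)
        csr = counts.tocsr()
        for j, gi in enumerate(idx_ok):
            row = csr.getrow(gi)
            sd = exp_sd[j]
            z0 = np.clip(-mean[gi] / sd, -clip, clip)
            z = np.clip((row.data - mean[gi]) / sd, -clip, clip)
            nz = len(z)
            s1 = z.sum() + z0 * (n_cells - nz)
            s2 = (z**2).sum() + z0**2 * (n_cells - nz)
            est_var[gi] = (s2 - s1**2 / n_cells) / max(n_cells - 1, 1)
    order = np.lexsort((matrix.gene_ids.astype(str), -est_var))
    return matrix.gene_ids[order[:n]]


def scale_regress(
    matrix: ExpressionMatrix,
    genes,
    covariate: np.ndarray,
    clip: float = 10.0,
) -> ExpressionMatrix:
    """Regress the covariate (typically percent mitochondrial UMIs) out of each
    gene's normalized expression, then z-score and clip the residuals.

    Genes with zero residual variance yield an all-zero scaled row.
    """
    genes = np.asarray(genes, dtype=object)
    X = matrix.normalized_dense(genes=genes)
    cov = np.asarray(covariate, dtype=np.float64)
    if len(cov) != matrix.n_cells:
        raise ValueError("covariate length must equal number of cells")
    design = np.column_stack([np.ones(matrix.n_cells), cov])
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    resid = X - (design @ beta).T
    sd = resid.std(axis=1, ddof=0)
    degenerate = sd <= 1e-12
    if degenerate.any():
        logger.warning("preprocess.scale_regress: %d zero-variance genes set to 0",
                       int(degenerate.sum()))
    sd[degenerate] = 1.0
    scaled = (resid - resid.mean(axis=1, keepdims=True)) / sd[:, None]
    scaled[degenerate] = 0.0
    np.clip(scaled, -clip, clip, out=scaled)
    matrix.scaled = scaled
    matrix.scaled_genes = genes
    return matrix
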