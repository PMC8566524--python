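"""Lineage annotation and malignant-cell discrimination.

Cells are labeled by Spearman correlation to bulk reference expression
profiles (a single-round correlation classifier over the most variable
reference genes); clusters inherit a lineage by majority vote; plasma cells
are gated within the B lineage by signature score and the Sdc1 > Cd19
marker ordering; and malignant plasma cells are separated from residual
normal plasma cells by transgene expression, cluster-wise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import embed_cluster
from .io_formats import ExpressionMatrix
from .preprocess import scale_regress, select_hvg

logger = logging.getLogger("mmprog")

UNASSIGNED = "unassigned"


def correlation_classify(
    matrix: ExpressionMatrix,
    reference_profiles: pd.DataFrame,
    variable_quantile: float = 0.8,
    min_shared_genes: int = 100,
) -> pd.DataFrame:
    """Label each cell with the reference profile it correlates best with.

    ``reference_profiles`` is genes x lineages (mean log-normalized
    expression per lineage). Correlations are Spearman, over the reference
    genes whose cross-lineage variance lies above ``variable_quantile``
    (restricted to genes present in the data). Ties break alphabetically;
    cells with undefined correlation (constant expression over the gene
    panel) are labeled ``unassigned``.
    """
    shared = [g for g in reference_profiles.index if g in set(matrix.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between data and reference "
            f"(need >= {min_shared_genes})"
        )
    ref = reference_profiles.loc[shared]
    var = ref.var(axis=1, ddof=0)
    cutoff = var.quantile(variable_quantile)
    panel = var.index[var >= cutoff]
    if len(panel) < 3:
        panel = var.index
    ref = ref.loc[panel]
    labels = sorted(ref.columns)

    X = matrix.normalized_dense(genes=np.asarray(panel, dtype=object))  # genes x cells
    # Spearman = Pearson on ranks
    Xr = stats.rankdata(X, axis=0)
    Rr = stats.rankdata(ref[labels].to_numpy(), axis=0)
    Xc = Xr - Xr.mean(axis=0, keepdims=True)
    Rc = Rr - Rr.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    rn = np.linalg.norm(Rc, axis=0)
    defined = (xn > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ Rc) / np.outer(np.where(defined, xn, 1.0), rn)
    corr[~defined] = np.nan

    best = []
    for j in range(matrix.n_cells):
        row = corr[j]
        if np.isnan(row).all():
            best.append(UNASSIGNED)
            continue
        m = np.nanmax(row)
        winners = [labels[i] for i in range(len(labels))
                   if not np.isnan(row[i]) and row[i] >= m - 1e-12]
        if len(winners) > 1:
            logger.warning("annotate.correlation_classify: tie for cell %s "
                           "broken alphabetically among %s",
                           matrix.cell_ids[j], winners)
        best.append(sorted(winners)[0])
    out = pd.DataFrame(corr, columns=labels)
    out.insert(0, "cell_id", matrix.cell_ids)
    out["best_label"] = best
    return out


def majority_annotate_clusters(
    lineage_calls: pd.DataFrame,
    cluster_labels: np.ndarray,
    target_labels,
    threshold: float = 0.5,
    annotation_name: str = "B_PC",
) -> pd.Series:
    """Annotate a cluster with the target lineage iff strictly more than
    ``threshold`` of its cells carry one of ``target_labels``; else "other"."""
    calls = lineage_calls["best_label"].to_numpy()
    clusters = np.asarray(cluster_labels)
    if len(calls) != len(clusters):
        raise ValueError("lineage calls and cluster labels must cover the same cells")
    targets = set(target_labels)
    out = {}
    for c in np.unique(clusters):
        members = calls[clusters == c]
        frac = np.isin(members, list(targets)).mean() if targets else 0.0
        out[c] = annotation_name if frac > threshold else "other"
    return pd.Series(out, name="annotation")


def call_plasma_cells(
    matrix: ExpressionMatrix,
    b_lineage_cells,
    b_cluster_labels: np.ndarray,
    plasma_scores: np.ndarray,
    markers: tuple[str, str] = ("Cd19", "Sdc1"),
) -> pd.Series:
    """Flag plasma-cell clusters within the B-lineage sub-clustering.

    A cluster is plasma iff its mean plasma-signature score is strictly
    positive and its mean Sdc1 (syndecan-1) normalized expression exceeds its
    mean Cd19. The flag propagates to member cells; returns a boolean Series
    indexed by cell id over ``b_lineage_cells``.
    """
    b_cells = np.asarray(b_lineage_cells, dtype=object)
    if len(b_cells) == 0:
        raise ValueError("B-lineage subset is empty")
    missing = [g for g in markers if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    cd19, sdc1 = markers
    expr = matrix.normalized_dense(genes=np.array([cd19, sdc1], dtype=object),
                                   cells=b_cells)
    clusters = np.asarray(b_cluster_labels)
    scores = np.asarray(plasma_scores, dtype=float)
    flags = np.zeros(len(b_cells), dtype=bool)
    for c in np.unique(clusters):
        m = clusters == c
        is_plasma = scores[m].mean() > 0 and expr[1, m].mean() > expr[0, m].mean()
        flags[m] = is_plasma
    logger.info("annotate.call_plasma_cells: %d / %d B-lineage cells flagged plasma",
                int(flags.sum()), len(b_cells))
    return pd.Series(flags, index=pd.Index(b_cells, name="cell_id"), name="is_plasma")


def _subcluster(matrix: ExpressionMatrix, cells, seed: int) -> np.ndarray:
    """Self-contained sub-clustering of a cell subset: normalize is assumed
    done; HVG -> scale -> PCA -> knee -> resolution-optimized Leiden."""
    sub = matrix.subset(cells=cells)
    n_hvg = min(1000, sub.n_genes)
    hvg = select_hvg(sub, n=n_hvg)
    totals = np.asarray(sub.counts.sum(axis=0)).ravel()
    # proxy covariate: log depth (mito content is unavailable on subsets)
    scale_regress(sub, hvg, np.log(totals))
    emb = embed_cluster.pca(sub, n_components=min(30, len(cells) - 1, n_hvg))
    k = embed_cluster.select_pcs_knee(emb.explained_variance)
    n_neighbors = min(20, len(cells) - 1)
    result = embed_cluster.optimize_resolution(
        sub, emb, k, resolutions=embed_cluster.MALIGNANT_RESOLUTIONS,
        min_de_genes=embed_cluster.MALIGNANT_MIN_DE_GENES,
        n_neighbors=n_neighbors, seed=seed,
    )
    return result.labels


def split_malignant(
    matrix: ExpressionMatrix,
    plasma_cells,
    transgene_id: str,
    sample_stages: pd.Series | None = None,
    cluster_labels: np.ndarray | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    control_stage: str = "control",
) -> pd.DataFrame:
    """Split plasma cells into malignant and residual normal cells.

    Plasma cells are sub-clustered; a cluster is called *normal* when its
    mean transgene expression is significantly lower than in every other
    cluster (one-sided rank-sum, Bonferroni over the comparisons) and below
    the global plasma-cell median; everything else is malignant. Plasma
    cells of control-stage samples are always normal.

    Parameters
    ----------
    sample_stages : optional per-cell stage labels (indexed by cell id) used
        for the control-sample override.
    cluster_labels : optional precomputed sub-clustering of the plasma cells;
        computed internally when omitted.
    """
    cells = np.asarray(plasma_cells, dtype=object)
    if len(cells) < 20:
        raise ValueError("need at least 20 plasma cells to split")
    if transgene_id not in set(matrix.gene_ids):
        raise ValueError(f"transgene {transgene_id!r} absent from matrix")
    tg = matrix.normalized_dense(genes=np.array([transgene_id], dtype=object),
                                 cells=cells).ravel()
    if cluster_labels is None:
        cluster_labels = _subcluster(matrix, cells, seed=seed)
    clusters = np.asarray(cluster_labels)
    uniq = np.unique(clusters)

    normal_clusters: set[int] = set()
    if len(uniq) < 2 or np.ptp(tg) == 0:
        if np.ptp(tg) == 0:
            logger.warning("annotate.split_malignant: no transgene variation; "
                           "all plasma cells flagged normal")
            normal_clusters = set(int(c) for c in uniq)
    else:
        global_median = float(np.median(tg))
        for c in uniq:
            m = clusters == c
            if tg[m].mean() >= global_median:
                continue
            pvals = []
            for d in uniq:
                if d == c:
                    continue
                # one-sided: cluster c lower than cluster d
                u = stats.mannwhitneyu(tg[m], tg[clusters == d],
                                       alternative="less", method="asymptotic")
                pvals.append(u.pvalue)
            if pvals and max(np.minimum(np.array(pvals) * len(pvals), 1.0)) < alpha:
                normal_clusters.add(int(c))

    is_normal = np.isin(clusters, list(normal_clusters))
    if sample_stages is not None:
        stages = sample_stages.reindex(cells).to_numpy()
        is_normal = is_normal | (stages == control_stage)
    out = pd.DataFrame({
        "cell_id": cells,
        "plasma_cluster": clusters,
        "transgene_expr": tg,
        "is_malignant": ~is_normal,
        "normal_cluster_flag": np.isin(clusters, list(normal_clusters)),
    })
    logger.info("annotate.split_malignant: %d malignant / %d normal plasma cells",
                int(out["is_malignant"].sum()), int((~out["is_malignant"]).sum()))
    return out
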