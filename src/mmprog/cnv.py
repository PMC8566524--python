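"""Expression-inferred copy-number analysis.

Malignant (observation) cells are compared to normal plasma (reference)
cells: per-gene log2 expression is centered by the reference mean, clamped,
smoothed by a chromosome-wise moving average in genomic order, re-centered
per cell, and denoised against the reference residual spread. Cells are
partitioned into CNV subpopulations by Ward clustering with a
silhouette-selected cut, and per-subpopulation gains/losses are called by
run-length thresholding of the mean smoothed profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .diffexpr import DeParams, hypergeom_enrich, wilcoxon_de
from .io_formats import NON_CNV_CHROMOSOMES, ExpressionMatrix, genomic_order

logger = logging.getLogger("mmprog")


@dataclass
class CnvProfile:
    cell_ids: np.ndarray
    ordered_genes: np.ndarray
    chromosomes: np.ndarray  # per ordered gene
    smoothed: np.ndarray  # cells x genes
    reference_sd: float
    subpop_labels: np.ndarray | None = None
    states: pd.DataFrame | None = None
    reference_smoothed: np.ndarray | None = None
    smoothed_raw: np.ndarray | None = None  # before denoising


def _moving_average_rows(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking windows at the
    edges (each position averages the values whose index is within
    window//2 of it)."""
    n = X.shape[1]
    half = window // 2
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1) + 1
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def _smooth_centered(
    centered: np.ndarray, chrom: np.ndarray, window: int
) -> np.ndarray:
    out = np.empty_like(centered)
    for c in pd.unique(chrom):
        m = chrom == c
        w = min(window, int(m.sum()))
        out[:, m] = _moving_average_rows(centered[:, m], w)
    return out


def infer_cnv_matrix(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    observation_cells,
    reference_cells,
    mean_cutoff: float = 0.1,
    window: int = 101,
    max_centered: float = 3.0,
    noise_sd_mult: float = 2.576,
    denoise: bool = True,
    scale: float = 10000.0,
) -> CnvProfile:
    """Reference-relative smoothed copy-number signal for observation cells.

    Genes with mean raw count below ``mean_cutoff`` (over observation and
    reference cells together), and genes on non-positional contigs
    (mitochondrial, transgene), are excluded. Values are log2 depth-
    normalized expression, reference-centered, clamped to
    ``±max_centered``, chromosome-wise moving-averaged, re-centered by each
    cell's median, and (optionally) set to 0 where within
    ``noise_sd_mult`` reference-residual standard deviations of 0. The
    default band (2.576 sd, the normal 99% band) suppresses well over 95%
    of null signal while leaving single-copy block-scale shifts intact.
    """
    obs = np.asarray(observation_cells, dtype=object)
    ref = np.asarray(reference_cells, dtype=object)
    if len(ref) == 0:
        raise ValueError("no reference cells")
    if len(obs) == 0:
        raise ValueError("no observation cells")

    ordered = genomic_order(annotation)
    ordered = ordered[~ordered["chromosome"].isin(NON_CNV_CHROMOSOMES)]
    ordered = ordered[ordered["gene_id"].isin(set(matrix.gene_ids))]
    genes = ordered["gene_id"].to_numpy(dtype=object)

    all_cells = np.concatenate([obs, ref])
    gi = matrix.gene_indexer(genes)
    ci = matrix.cell_indexer(all_cells)
    counts = matrix.counts[gi][:, ci]
    mean_count = np.asarray(counts.mean(axis=1)).ravel()
    keep = mean_count >= mean_cutoff
    genes = genes[keep]
    chrom = ordered["chromosome"].to_numpy(dtype=object)[keep]
    counts = counts[keep]
    logger.info("cnv.infer_cnv_matrix: %d genes pass mean cutoff %.2f",
                len(genes), mean_cutoff)

    totals = np.asarray(matrix.counts[:, ci].sum(axis=0)).ravel()
    dense = np.asarray(counts.todense(), dtype=np.float64)
    expr = np.log2(dense / totals[None, :] * scale + 1.0)  # genes x cells

    n_obs = len(obs)
    ref_mean = expr[:, n_obs:].mean(axis=1)
    centered = (expr - ref_mean[:, None]).T  # cells x genes
    np.clip(centered, -max_centered, max_centered, out=centered)

    smoothed = _smooth_centered(centered, chrom, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    ref_sm = smoothed[n_obs:]
    ref_sd = float(ref_sm.std(ddof=0)) if ref_sm.size else 0.0
    obs_sm = smoothed[:n_obs].copy()
    if denoise and ref_sd > 0:
        obs_sm[np.abs(obs_sm) < noise_sd_mult * ref_sd] = 0.0
        ref_den = ref_sm.copy()
        ref_den[np.abs(ref_den) < noise_sd_mult * ref_sd] = 0.0
    else:
        ref_den = ref_sm
    return CnvProfile(
        cell_ids=obs, ordered_genes=genes,
        chromosomes=np.asarray(chrom, dtype=object),
        smoothed=obs_sm, reference_sd=ref_sd, reference_smoothed=ref_den,
        smoothed_raw=smoothed[:n_obs].copy(),
    )


def _chromosome_means(profile: CnvProfile) -> np.ndarray:
    """Per-cell mean smoothed signal per chromosome (cells x chromosomes).

    The moving average leaves noise that is correlated over a window's
    length, so gene-level Euclidean distances are dominated by it;
    averaging within chromosomes is the natural summary for the
    chromosome-arm-scale dosage events the partition is after.
    """
    base = (profile.smoothed_raw if profile.smoothed_raw is not None
            else profile.smoothed)
    chroms = pd.unique(profile.chromosomes)
    out = np.empty((base.shape[0], len(chroms)))
    for j, c in enumerate(chroms):
        out[:, j] = base[:, profile.chromosomes == c].mean(axis=1)
    return out


def partition_subpopulations(
    profile: CnvProfile,
    min_subpop: int = 3,
    max_subpops: int = 12,
    silhouette_floor: float = 0.2,
) -> np.ndarray:
    """Ward-linkage partition of cells by chromosome-level CNV signal.

    Cells are clustered on their per-chromosome mean smoothed values.
    Candidate cuts of 2..``max_subpops`` groups are scored by mean
    silhouette; the best cut is kept if its silhouette reaches
    ``silhouette_floor``, otherwise all cells form a single subpopulation
    (the one-group "cut"). Subpopulations smaller than ``min_subpop`` are
    merged into the nearest (by centroid distance) larger subpopulation.
    Labels are renumbered by decreasing size.
    """
    X = _chromosome_means(profile)
    n = X.shape[0]
    if n < max(min_subpop, 2):
        labels = np.zeros(n, dtype=int)
        profile.subpop_labels = labels
        return labels
    Z = linkage(X, method="ward")
    best_k, best_s = 1, -np.inf
    for k in range(2, min(max_subpops, n - 1) + 1):
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        s = silhouette_score(X, lab, metric="euclidean")
        if s > best_s:
            best_k, best_s = k, s
    if best_s < silhouette_floor:
        best_k = 1
    labels = (fcluster(Z, t=best_k, criterion="maxclust") - 1
              if best_k > 1 else np.zeros(n, dtype=int))

    # polish the greedy Ward boundaries: reassign each cell to the nearest
    # subpopulation centroid until stable (k-means refinement at fixed k)
    for _ in range(10):
        cents = np.stack([X[labels == c].mean(axis=0)
                          for c in np.unique(labels)])
        d = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        new = np.unique(labels)[d.argmin(axis=1)]
        if (new == labels).all():
            break
        labels = new

    # merge undersized subpopulations into the nearest sibling by centroid
    sizes = pd.Series(labels).value_counts()
    small = [c for c in sizes.index if sizes[c] < min_subpop]
    big = [c for c in sizes.index if sizes[c] >= min_subpop]
    if small and big:
        centroids = {c: X[labels == c].mean(axis=0) for c in np.unique(labels)}
        for c in small:
            d = {b: np.linalg.norm(centroids[c] - centroids[b]) for b in big}
            target = min(sorted(d), key=lambda b: d[b])
            logger.info("cnv.partition_subpopulations: merged subpop %s (%d "
                        "cells) into %s", c, sizes[c], target)
            labels[labels == c] = target
    order = pd.Series(labels).value_counts().index
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in labels], dtype=int)
    profile.subpop_labels = labels
    return labels


def call_states(
    profile: CnvProfile,
    subpop_labels: np.ndarray | None = None,
    loss_thresh: float = -0.1,
    gain_thresh: float = 0.1,
    min_run: int = 20,
) -> pd.DataFrame:
    """Discrete loss/neutral/gain calls per subpopulation.

    The mean smoothed profile of each subpopulation is scanned chromosome-
    wise for maximal runs of at least ``min_run`` consecutive genes beyond a
    threshold; those genes are called loss/gain, all else neutral. Returns a
    long table (subpop, gene, chromosome, state) plus a ``runs`` attribute-
    style summary accessible via groupby.
    """
    labels = profile.subpop_labels if subpop_labels is None else np.asarray(subpop_labels)
    if labels is None:
        raise ValueError("partition not computed")
    rows = []
    for sp in np.unique(labels):
        mean_prof = profile.smoothed[labels == sp].mean(axis=0)
        state = np.array(["neutral"] * len(mean_prof), dtype=object)
        for c in pd.unique(profile.chromosomes):
            m = np.flatnonzero(profile.chromosomes == c)
            for name, cond in (("loss", mean_prof[m] <= loss_thresh),
                               ("gain", mean_prof[m] >= gain_thresh)):
                run_start = None
                padded = np.concatenate([cond, [False]])
                for i, flag in enumerate(padded):
                    if flag and run_start is None:
                        run_start = i
                    elif not flag and run_start is not None:
                        if i - run_start >= min_run:
                            state[m[run_start:i]] = name
                        run_start = None
        rows.append(pd.DataFrame({
            "subpop": sp,
            "gene": profile.ordered_genes,
            "chromosome": profile.chromosomes,
            "state": state,
        }))
    states = pd.concat(rows, ignore_index=True)
    profile.states = states
    return states


def map_subpops_to_clusters(
    subpop_labels: pd.Series,
    cluster_labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency of CNV subpopulations against transcriptional clusters.

    Both inputs are indexed by cell id and must cover the same cells.
    Returns the contingency table and a two-part summary: per cluster, the
    majority subpopulation and its fraction of the cluster; per
    subpopulation, the majority cluster and the fraction of the
    subpopulation it holds (a subclone spread uniformly over k clusters has
    majority fraction ~1/k).
    """
    if set(subpop_labels.index) != set(cluster_labels.index):
        raise ValueError("subpopulation and cluster labels cover different cells")
    cluster_labels = cluster_labels.reindex(subpop_labels.index)
    table = pd.crosstab(subpop_labels, cluster_labels)
    table.index.name = "subpop"
    table.columns.name = "cluster"
    rows = []
    for cl in table.columns:
        col = table[cl]
        rows.append(("cluster", cl, col.idxmax(), col.max() / col.sum()))
    for sp in table.index:
        row = table.loc[sp]
        rows.append(("subpop", sp, row.idxmax(), row.max() / row.sum()))
    summary = pd.DataFrame(rows, columns=["axis", "label", "majority",
                                          "majority_fraction"])
    return table, summary


def subpop_cluster_count_correlation(
    n_subpops: np.ndarray, n_clusters: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between per-sample CNV
    subpopulation counts and transcriptional cluster counts."""
    x = np.asarray(n_subpops, dtype=float)
    y = np.asarray(n_clusters, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def subpop_marker_analysis(
    matrix: ExpressionMatrix,
    cells_with_state,
    other_malignant_cells,
    gene_sets: dict[str, set[str]],
    de_params: DeParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker genes of a CNV state's carrier cells versus the remaining
    malignant cells (rank-sum at the CNV-marker thresholds), followed by
    over-representation of the upregulated markers."""
    carriers = np.asarray(cells_with_state, dtype=object)
    others = np.asarray(other_malignant_cells, dtype=object)
    if len(carriers) == 0 or len(others) == 0:
        raise ValueError("both carrier and comparison groups must be non-empty")
    de = wilcoxon_de(matrix, carriers, others, de_params or DeParams.cnv_markers())
    up = de.loc[de["significant"] & (de["logfc"] > 0), "gene"].tolist()
    if up:
        enrich = hypergeom_enrich(up, matrix.gene_ids, gene_sets)
    else:
        enrich = pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p", "fdr", "significant"])
    return de, enrich
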