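"""PCA embedding, knee-point PC selection, shared-nearest-neighbor graph
clustering, and the DE-constrained multi-resolution optimizer.

The optimizer scans a resolution grid, keeps only resolutions whose every
cluster has at least a minimum number of significant one-vs-rest marker
genes, and among those returns the clustering with the greatest median of
per-cluster mean silhouettes (computed in the clustering PC space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .diffexpr import DeParams, wilcoxon_de
from .io_formats import ExpressionMatrix

logger = logging.getLogger("mmprog")

#: default resolution grids: finer for within-tumour malignant subsets,
#: coarser-to-finer for the whole lineage-level dataset
MALIGNANT_RESOLUTIONS: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4)
LINEAGE_RESOLUTIONS: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
MALIGNANT_MIN_DE_GENES = 5
LINEAGE_MIN_DE_GENES = 15


@dataclass
class Embedding:
    cell_ids: np.ndarray
    coordinates: np.ndarray  # cells x k
    explained_variance: np.ndarray  # length k, non-increasing


@dataclass
class ClusteringResult:
    resolution: float
    labels: np.ndarray
    admissible: bool
    per_cluster_silhouette: dict[int, float]
    median_silhouette: float
    scan: pd.DataFrame = field(default_factory=pd.DataFrame)


def pca(matrix: ExpressionMatrix, n_components: int = 50) -> Embedding:
    """PCA of the scaled layer (cells as observations, variable genes as
    features). Component signs are fixed so the largest-magnitude loading of
    each component is positive, making the embedding deterministic."""
    if matrix.scaled is None:
        raise ValueError("scaled layer not computed")
    X = matrix.scaled.T  # cells x genes
    max_rank = min(X.shape)
    k = min(n_components, max_rank)
    if k < n_components:
        logger.warning("embed_cluster.pca: n_components truncated to rank %d", k)
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    # deterministic sign convention
    for j in range(k):
        load = model.components_[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            coords[:, j] *= -1
            model.components_[j] *= -1
    return Embedding(
        cell_ids=matrix.cell_ids.copy(),
        coordinates=coords,
        explained_variance=model.explained_variance_.copy(),
    )


def select_pcs_knee(explained_variance: np.ndarray) -> int:
    """Knee-point choice of the number of informative components.

    Finds the scree point with maximum perpendicular distance to the chord
    joining the first and last points (axes rescaled to the unit square);
    components strictly before that point are retained, with a floor of 2.
    """
    v = np.asarray(explained_variance, dtype=np.float64)
    n = len(v)
    if n < 3:
        return max(2, n)
    x = np.arange(1, n + 1, dtype=np.float64)
    span = v[0] - v[-1]
    if span <= 0:
        logger.warning("embed_cluster.select_pcs_knee: flat variance sequence; k=2")
        return 2
    xn = (x - 1) / (n - 1)
    yn = (v - v[-1]) / span
    # chord runs from (0, 1) to (1, 0); distance ∝ |x + y - 1|
    dist = np.abs(xn + yn - 1.0)
    if dist.max() < 1e-9:  # linear decay: chord coincides with the curve
        logger.warning("embed_cluster.select_pcs_knee: degenerate scree; k=2")
        return 2
    knee = int(np.argmax(dist)) + 1  # 1-based knee point
    return max(2, knee - 1)


def snn_graph(coords: np.ndarray, n_neighbors: int = 20,
              prune: float = 1.0 / 15.0) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN lists
    (self-inclusive), edges below ``prune`` dropped."""
    n = coords.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors, algorithm="auto")
    nn.fit(coords)
    knn = nn.kneighbors(coords, return_distance=False)
    rows = np.repeat(np.arange(n), n_neighbors)
    adj = sparse.csr_matrix(
        (np.ones(n * n_neighbors), (rows, knn.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |N(i) ∩ N(j)|
    shared = shared.tocoo()
    jac = shared.data / (2 * n_neighbors - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    return sparse.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster_graph(
    embedding: Embedding,
    k_pcs: int,
    resolution: float,
    n_neighbors: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Leiden modularity communities on the SNN graph built in the first
    ``k_pcs`` components. Labels are renumbered by decreasing cluster size
    (ties by first occurrence) and are deterministic for a fixed seed."""
    coords = embedding.coordinates[:, :k_pcs]
    g = snn_graph(coords, n_neighbors=n_neighbors)
    g = g.maximum(g.T)  # symmetrize
    coo = sparse.triu(g, k=1).tocoo()
    graph = igraph.Graph(
        n=coords.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # stable renumbering: largest cluster first
    sizes = pd.Series(raw).value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index)}
    return np.array([mapping[x] for x in raw], dtype=int)


def silhouette_summary(
    embedding: Embedding, k_pcs: int, labels: np.ndarray
) -> tuple[dict[int, float], float]:
    """Per-cluster mean silhouettes (Euclidean, in PC space) and their median.

    Cells in singleton clusters receive silhouette 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    coords = embedding.coordinates[:, :k_pcs]
    s = silhouette_samples(coords, labels, metric="euclidean")
    sizes = pd.Series(labels).value_counts()
    singletons = set(sizes.index[sizes == 1])
    if singletons:
        logger.warning("embed_cluster.silhouette_summary: %d singleton clusters "
                       "assigned silhouette 0", len(singletons))
        s = np.where(np.isin(labels, list(singletons)), 0.0, s)
    per_cluster = {int(c): float(s[labels == c].mean()) for c in uniq}
    median = float(np.median(list(per_cluster.values())))
    return per_cluster, median


def optimize_resolution(
    matrix: ExpressionMatrix,
    embedding: Embedding,
    k_pcs: int,
    resolutions=MALIGNANT_RESOLUTIONS,
    min_de_genes: int = MALIGNANT_MIN_DE_GENES,
    de_params: DeParams | None = None,
    n_neighbors: int = 20,
    seed: int = 0,
) -> ClusteringResult:
    """Scan a resolution grid and select by the DE-constrained silhouette rule.

    A resolution is admissible when every one of its clusters has at least
    ``min_de_genes`` significant one-vs-rest marker genes (Wilcoxon at the
    marker thresholds). Among admissible resolutions the one with the
    greatest median per-cluster mean silhouette wins; exact ties go to the
    lowest resolution. With no admissible resolution, the resolution with
    the fewest clusters is returned flagged ``admissible=False``.
    """
    de_params = de_params or DeParams.markers()
    rows = []
    candidates: dict[float, tuple[np.ndarray, dict[int, float], float]] = {}
    for res in resolutions:
        labels = cluster_graph(embedding, k_pcs, resolution=res,
                               n_neighbors=n_neighbors, seed=seed)
        uniq = np.unique(labels)
        if len(uniq) < 2:
            rows.append((res, len(uniq), False, 0, np.nan))
            continue
        min_markers = np.inf
        ok = True
        for c in uniq:
            in_c = embedding.cell_ids[labels == c]
            rest = embedding.cell_ids[labels != c]
            de = wilcoxon_de(matrix, in_c, rest, de_params)
            n_sig = int(de["significant"].sum())
            min_markers = min(min_markers, n_sig)
            if n_sig < min_de_genes:
                ok = False
        per_cluster, median = silhouette_summary(embedding, k_pcs, labels)
        rows.append((res, len(uniq), ok,
                     0 if np.isinf(min_markers) else int(min_markers), median))
        if ok:
            candidates[res] = (labels, per_cluster, median)
    scan = pd.DataFrame(
        rows, columns=["resolution", "n_clusters", "admissible",
                       "min_cluster_de_genes", "median_silhouette"]
    )

    if candidates:
        best_res = max(sorted(candidates), key=lambda r: candidates[r][2])
        # max() keeps the first (lowest) resolution on exact ties
        labels, per_cluster, median = candidates[best_res]
        result = ClusteringResult(best_res, labels, True, per_cluster, median, scan)
    else:
        logger.warning("embed_cluster.optimize_resolution: no admissible "
                       "resolution; falling back to fewest clusters")
        fallback = scan.sort_values(["n_clusters", "resolution"]).iloc[0]
        res = float(fallback["resolution"])
        labels = cluster_graph(embedding, k_pcs, resolution=res,
                               n_neighbors=n_neighbors, seed=seed)
        if len(np.unique(labels)) >= 2:
            per_cluster, median = silhouette_summary(embedding, k_pcs, labels)
        else:
            per_cluster, median = {0: 0.0}, 0.0
        result = ClusteringResult(res, labels, False, per_cluster, median, scan)
    logger.info("embed_cluster.optimize_resolution: selected res=%.2f "
                "(admissible=%s, %d clusters)", result.resolution,
                result.admissible, len(np.unique(result.labels)))
    return result
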