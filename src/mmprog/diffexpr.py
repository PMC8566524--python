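"""Wilcoxon rank-sum differential expression with detection/fold-change
prefilters and the small-group exact null distribution, plus hypergeometric
gene-set over-representation.

Testing policy
--------------
A gene enters the rank-sum test only when it is detected in more than
``min_detect_frac`` of either group *and* its |log fold change| exceeds
``min_logfc``, where the fold change is computed on de-logged normalized
means with a pseudocount of ``1 / (n_A + n_B)``:

    logFC = ln(mean(exp(x_A) - 1) + pc) - ln(mean(exp(x_B) - 1) + pc)

Bonferroni correction multiplies by the number of genes actually tested.
When both groups have at most ``exact_max`` cells (default 25) the exact
permutation null of the rank sum is used (ties included); otherwise the
normal approximation with tie correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger("mmprog")


@dataclass
class DeParams:
    """Thresholds for one DE run.

    Defaults follow the stage/population comparison convention (30%
    detection, 0.5 ln-fold); cluster-marker runs use
    :func:`DeParams.markers` (25% / 0.25).
    """

    min_detect_frac: float = 0.30
    min_logfc: float = 0.5
    alpha: float = 0.05
    exact_max: int = 25

    @classmethod
    def markers(cls) -> "DeParams":
        return cls(min_detect_frac=0.25, min_logfc=0.25)

    @classmethod
    def cnv_markers(cls) -> "DeParams":
        return cls(min_detect_frac=0.25, min_logfc=1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.min_detect_frac <= 1):
            raise ValueError("min_detect_frac must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _exact_ranksum_pvalue(ranks_a: np.ndarray, pooled_ranks: np.ndarray) -> float:
    """Two-sided exact p for the rank sum of group A.

    p = P(|W - E[W]| >= |w - E[W]|) under uniformly random assignment of
    group labels, computed by dynamic programming over the pooled rank
    multiset (ties enter through midranks). Ranks are doubled so midranks
    become integers.
    """
    r2 = np.round(pooled_ranks * 2).astype(np.int64)
    n1 = len(ranks_a)
    w2 = int(round(ranks_a.sum() * 2))
    total = int(r2.sum())
    # dp[k, s] = number of k-subsets of the processed ranks with doubled sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        # iterate k downward so each rank is used at most once
        for k in range(min(n1, 1_000_000), 0, -1):
            if k > n1:
                continue
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    mean2 = float((r2.sum() / len(r2)) * n1)
    dev = abs(w2 - mean2)
    support = np.flatnonzero(dist)
    mask = np.abs(support - mean2) >= dev - 1e-9
    return float(dist[support][mask].sum() / n_total)


def _asymptotic_ranksum_p(W: np.ndarray, n1: int, n2: int,
                          tie_term: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation p for rank sums W of group A.

    ``tie_term`` is sum(t^3 - t) over tie groups, per gene.
    """
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 1e-300)
    z = (W - mu) / np.sqrt(var)
    return 2.0 * stats.norm.sf(np.abs(z))


def _rank_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks along axis 1 and the per-row tie correction term."""
    n_rows, n = X.shape
    ranks = np.empty_like(X, dtype=np.float64)
    tie_term = np.zeros(n_rows)
    for i in range(n_rows):
        r = stats.rankdata(X[i], method="average")
        ranks[i] = r
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = float((counts.astype(np.float64) ** 3 - counts).sum())
    return ranks, tie_term


def wilcoxon_de(
    matrix: ExpressionMatrix,
    group_a_cells,
    group_b_cells,
    params: DeParams | None = None,
    genes=None,
) -> pd.DataFrame:
    """Rank-sum DE of group A versus group B on the normalized layer.

    Returns one row per *tested* gene with columns gene, logfc, p, p_adj
    (Bonferroni over tested genes), frac_a, frac_b, significant.
    """
    params = params or DeParams()
    a_idx = matrix.cell_indexer(group_a_cells)
    b_idx = matrix.cell_indexer(group_b_cells)
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")

    gene_ids = matrix.gene_ids if genes is None else np.asarray(genes, dtype=object)
    gi = matrix.gene_indexer(gene_ids)
    norm = matrix.normalized
    if norm is None:
        raise ValueError("normalized layer not computed")
    # prefilters computed sparsely; only tested genes are densified
    SA = norm[gi][:, a_idx].tocsr()
    SB = norm[gi][:, b_idx].tocsr()
    n1, n2 = len(a_idx), len(b_idx)
    frac_a = SA.getnnz(axis=1) / n1
    frac_b = SB.getnnz(axis=1) / n2
    pc = 1.0 / (n1 + n2)
    EA, EB = SA.copy(), SB.copy()
    EA.data = np.expm1(EA.data)
    EB.data = np.expm1(EB.data)
    logfc = (np.log(np.asarray(EA.sum(axis=1)).ravel() / n1 + pc)
             - np.log(np.asarray(EB.sum(axis=1)).ravel() / n2 + pc))

    tested = ((frac_a > params.min_detect_frac) | (frac_b > params.min_detect_frac)) \
        & (np.abs(logfc) > params.min_logfc)
    idx = np.flatnonzero(tested)
    n_tested = len(idx)
    if n_tested == 0:
        return pd.DataFrame(columns=["gene", "logfc", "p", "p_adj",
                                     "frac_a", "frac_b", "significant"])

    X = np.concatenate([np.asarray(SA[idx].todense()),
                        np.asarray(SB[idx].todense())], axis=1)
    exact = n1 <= params.exact_max and n2 <= params.exact_max
    if exact:
        p = np.array([
            _exact_ranksum_pvalue(
                stats.rankdata(X[i], method="average")[:n1],
                stats.rankdata(X[i], method="average"),
            )
            for i in range(n_tested)
        ])
    else:
        ranks, tie_term = _rank_matrix(X)
        W = ranks[:, :n1].sum(axis=1)
        p = _asymptotic_ranksum_p(W, n1, n2, tie_term)
    p = np.minimum(p, 1.0)
    p_adj = np.minimum(p * n_tested, 1.0)
    out = pd.DataFrame({
        "gene": gene_ids[idx],
        "logfc": logfc[idx],
        "p": p,
        "p_adj": p_adj,
        "frac_a": frac_a[idx],
        "frac_b": frac_b[idx],
    })
    out["significant"] = out["p_adj"] < params.alpha
    out = out.sort_values(["p_adj", "gene"], kind="mergesort").reset_index(drop=True)
    logger.info("diffexpr.wilcoxon_de: %d vs %d cells, %d tested, %d significant",
                n1, n2, n_tested, int(out["significant"].sum()))
    return out


def wilcoxon_raw_pvalues(matrix: ExpressionMatrix, group_a_cells, group_b_cells,
                         genes=None) -> pd.Series:
    """Unfiltered two-sided rank-sum p-values for every gene (normal
    approximation with tie correction); used for calibration checks."""
    a_idx = matrix.cell_indexer(group_a_cells)
    b_idx = matrix.cell_indexer(group_b_cells)
    gene_ids = matrix.gene_ids if genes is None else np.asarray(genes, dtype=object)
    gi = matrix.gene_indexer(gene_ids)
    A = np.asarray(matrix.normalized[gi][:, a_idx].todense())
    B = np.asarray(matrix.normalized[gi][:, b_idx].todense())
    X = np.concatenate([A, B], axis=1)
    ranks, tie_term = _rank_matrix(X)
    W = ranks[:, : A.shape[1]].sum(axis=1)
    p = _asymptotic_ranksum_p(W, A.shape[1], B.shape[1], tie_term)
    return pd.Series(np.minimum(p, 1.0), index=gene_ids, name="p")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-free)."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def hypergeom_enrich(
    marker_genes,
    universe,
    gene_sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of markers in each gene set.

    P[X >= k] with N = |universe|, K = |set ∩ universe|, n = |markers|,
    k = |markers ∩ set|; BH-FDR across sets.
    """
    universe = set(universe)
    markers = set(marker_genes)
    if not universe:
        raise ValueError("empty universe")
    if not markers:
        raise ValueError("empty marker list")
    if not markers <= universe:
        raise ValueError("marker genes must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        k = len(markers & members)
        K, n, N = len(members), len(markers), len(universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < alpha
    return out.sort_values(["fdr", "term"], kind="mergesort").reset_index(drop=True)
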