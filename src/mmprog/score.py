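"""Gene-module scoring with expression-matched binned controls, cell-cycle
phase assignment, and bulk signature scoring.

The per-cell module score is the mean normalized expression of the
signature genes minus the mean over control genes drawn from the same
average-expression bins, which removes the depth/complexity component a raw
signature mean would carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

logger = logging.getLogger("mmprog")


@dataclass
class ModuleScoreParams:
    n_control_per_gene: int = 25
    n_bins: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_per_gene < 1:
            raise ValueError("n_control_per_gene must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _expression_bins(matrix: ExpressionMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of genes by average normalized expression."""
    if matrix.normalized is None:
        raise ValueError("normalized layer not computed")
    avg = np.asarray(matrix.normalized.mean(axis=1)).ravel()
    # rank-based cut gives equal-frequency bins and is stable under ties
    ranks = pd.Series(avg).rank(method="first").to_numpy()
    return np.ceil(ranks / len(ranks) * n_bins).astype(int) - 1


def module_score(
    matrix: ExpressionMatrix,
    gene_set,
    params: ModuleScoreParams | None = None,
) -> np.ndarray:
    """Per-cell score of one gene signature against binned controls.

    For each signature gene, ``n_control_per_gene`` control genes are drawn
    (seeded, without replacement where the bin allows, otherwise with
    replacement and a warning) from its average-expression bin; the score is
    mean(signature) - mean(unique control genes) of normalized expression.
    Signature genes absent from the matrix are dropped with a warning.
    """
    params = params or ModuleScoreParams()
    present = [g for g in gene_set if g in set(matrix.gene_ids)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.warning("score.module_score: %d signature genes absent: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no signature gene present in the matrix")
    present = sorted(present)

    bins = _expression_bins(matrix, params.n_bins)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    sig_idx = np.array([gene_pos[g] for g in present])
    sig_set = set(sig_idx.tolist())

    rng = np.random.default_rng(params.seed)
    control_idx: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[pool != gi]
        if len(pool) == 0:
            logger.warning("score.module_score: no control candidates in bin "
                           "of gene %s", matrix.gene_ids[gi])
            continue
        replace = len(pool) < params.n_control_per_gene
        if replace:
            logger.warning("score.module_score: bin of gene %s has only %d "
                           "candidates; sampling with replacement",
                           matrix.gene_ids[gi], len(pool))
        draw = rng.choice(pool, size=params.n_control_per_gene, replace=replace)
        control_idx.update(int(x) for x in draw)
    control_idx -= sig_set
    if not control_idx:
        raise ValueError("no control genes could be drawn")
    ctrl = np.array(sorted(control_idx))

    norm = matrix.normalized
    sig_mean = np.asarray(norm[sig_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm[ctrl].mean(axis=0)).ravel()
    return sig_mean - ctrl_mean


def assign_cell_cycle(
    matrix: ExpressionMatrix,
    s_genes,
    g2m_genes,
    params: ModuleScoreParams | None = None,
) -> pd.DataFrame:
    """Score S and G2/M signatures and assign a phase per cell.

    The phase is the signature with the highest positive score; G1 when both
    scores are negative or zero. An exact positive tie goes to G2M.
    """
    params = params or ModuleScoreParams()
    s_score = module_score(matrix, s_genes, params)
    g2m_score = module_score(
        matrix, g2m_genes,
        ModuleScoreParams(params.n_control_per_gene, params.n_bins, params.seed + 1),
    )
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0), "G1",
        np.where(g2m_score >= s_score, "G2M", "S"),
    )
    return pd.DataFrame({"cell_id": matrix.cell_ids, "s_score": s_score,
                         "g2m_score": g2m_score, "phase": phase})


def bulk_signature_score(bulk_matrix: pd.DataFrame, gene_set) -> pd.Series:
    """Mean scaled-expression score of a gene set per bulk sample.

    ``bulk_matrix`` is samples x genes. Each set gene is z-scored across
    samples (population sd); zero-variance genes are dropped with a warning.
    """
    present = [g for g in sorted(set(gene_set)) if g in bulk_matrix.columns]
    if not present:
        raise ValueError("no gene-set gene present in the bulk matrix")
    X = bulk_matrix[present].to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if (~keep).any():
        dropped = [g for g, k in zip(present, keep) if not k]
        logger.warning("score.bulk_signature_score: dropped %d zero-variance "
                       "genes: %s", len(dropped), dropped[:5])
    if not keep.any():
        raise ValueError("all gene-set genes have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return pd.Series(Z.mean(axis=1), index=bulk_matrix.index, name="score")
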