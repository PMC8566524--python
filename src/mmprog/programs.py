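"""Program discovery across disease stages and tumours.

Three procedures operate on malignant cells:

* **core program** — genes differentially expressed (same direction) between
  malignant cells and normal plasma cells at *every* disease stage;
* **temporal genes** — per-sample DE against other-stage malignant cells,
  out-group detection filtering, within-stage intersection, then pairwise
  t-tests of per-sample means to classify each gene's longitudinal pattern
  (decreasing / peak-early / peak-intermediate);
* **similarity programs** — per-sample transcriptional clusters represented
  by their significantly enriched term sets, compared pairwise by Jaccard
  index and grouped by complete-linkage hierarchical clustering.

Plus the cohort-level association between per-sample malignant fraction and
the serum M-protein surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import DeParams, bh_adjust, hypergeom_enrich, wilcoxon_de
from .io_formats import ExpressionMatrix

logger = logging.getLogger("mmprog")

DISEASE_STAGES = ("early", "intermediate", "active")


@dataclass
class CoreProgram:
    up_genes: set[str]
    down_genes: set[str]
    stage_tables: dict[str, pd.DataFrame]


@dataclass
class ProgramSimilarity:
    cluster_keys: list[str]  # "sample:cluster"
    jaccard: pd.DataFrame  # symmetric, unit diagonal
    assignments: pd.Series  # cluster key -> program id
    mean_within: dict[str, float]
    mean_between: float
    term_sets: dict[str, set[str]] = field(default_factory=dict)


def core_program(
    matrix: ExpressionMatrix,
    malignant_by_stage: dict[str, np.ndarray],
    normal_pc_cells,
    de_params: DeParams | None = None,
) -> CoreProgram:
    """Genes consistently up/down in malignant cells versus normal plasma
    cells across all disease stages.

    ``malignant_by_stage`` maps each disease stage to its malignant cell
    ids; each stage is compared to the pooled normal plasma cells and the
    significant up (down) sets are intersected across stages.
    """
    de_params = de_params or DeParams()
    normal = np.asarray(normal_pc_cells, dtype=object)
    if len(normal) < 20:
        raise ValueError("need >= 20 normal plasma cells as reference")
    tables: dict[str, pd.DataFrame] = {}
    up_sets, down_sets = [], []
    for stage in DISEASE_STAGES:
        cells = np.asarray(malignant_by_stage.get(stage, []), dtype=object)
        if len(cells) == 0:
            raise ValueError(f"stage {stage!r} has no malignant cells")
        de = wilcoxon_de(matrix, cells, normal, de_params)
        tables[stage] = de
        sig = de[de["significant"]]
        up_sets.append(set(sig.loc[sig["logfc"] > 0, "gene"]))
        down_sets.append(set(sig.loc[sig["logfc"] < 0, "gene"]))
    up = set.intersection(*up_sets)
    down = set.intersection(*down_sets)
    logger.info("programs.core_program: %d up, %d down core genes",
                len(up), len(down))
    return CoreProgram(up_genes=up, down_genes=down, stage_tables=tables)


def stage_specific_candidates(
    matrix: ExpressionMatrix,
    malignant_cells_by_sample: dict[str, np.ndarray],
    sample_stages: dict[str, str],
    de_params: DeParams | None = None,
    outgroup_max_frac: float = 0.30,
) -> dict[str, set[str]]:
    """Per-stage candidate temporal genes.

    Each sample's malignant cells are compared to the pooled malignant cells
    of the *other* stages; upregulated significant genes are kept only when
    detected in at most ``outgroup_max_frac`` of the out-group cells, and
    each stage's candidates are the intersection across its usable samples.
    Samples without malignant cells are skipped with a log line.
    """
    de_params = de_params or DeParams()
    by_stage: dict[str, list[str]] = {s: [] for s in DISEASE_STAGES}
    for sample, stage in sample_stages.items():
        if stage in by_stage:
            by_stage[stage].append(sample)

    candidates: dict[str, set[str]] = {}
    for stage in DISEASE_STAGES:
        outgroup = np.concatenate([
            np.asarray(malignant_cells_by_sample.get(s, []), dtype=object)
            for s, st in sample_stages.items()
            if st in DISEASE_STAGES and st != stage
        ] or [np.array([], dtype=object)])
        per_sample_sets: list[set[str]] = []
        for sample in by_stage[stage]:
            cells = np.asarray(malignant_cells_by_sample.get(sample, []),
                               dtype=object)
            if len(cells) == 0:
                logger.info("programs.stage_specific_candidates: sample %s has "
                            "no malignant cells; skipped", sample)
                continue
            de = wilcoxon_de(matrix, cells, outgroup, de_params)
            up = de[(de["significant"]) & (de["logfc"] > 0)
                    & (de["frac_b"] <= outgroup_max_frac)]
            per_sample_sets.append(set(up["gene"]))
        if not per_sample_sets:
            raise ValueError(f"stage {stage!r} has no usable sample")
        candidates[stage] = set.intersection(*per_sample_sets)
        logger.info("programs.stage_specific_candidates: stage %s -> %d candidates",
                    stage, len(candidates[stage]))
    return candidates


def _pattern(means: dict[str, float], sig: dict[tuple[str, str], bool]) -> str:
    """Classify a per-stage mean profile. Checked in order: decreasing,
    peak-early, peak-intermediate; anything else is 'other'."""
    e, i, a = means["early"], means["intermediate"], means["active"]
    ea = sig.get(("early", "active"), False)
    if e > i > a and ea:
        return "decreasing"
    if e > i and e > a and ea:
        return "peak_early"
    if i > e and i > a and (sig.get(("early", "intermediate"), False)
                            or sig.get(("intermediate", "active"), False)):
        return "peak_intermediate"
    return "other"


def temporal_classify(
    matrix: ExpressionMatrix,
    candidates,
    malignant_cells_by_sample: dict[str, np.ndarray],
    sample_stages: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify candidate genes by their per-stage mean expression profile.

    For each gene, per-sample means of normalized expression over malignant
    cells are compared between stage pairs by unpaired two-sided t-tests,
    Bonferroni-corrected over the three pairwise comparisons; a gene is
    retained when at least one adjusted comparison is significant. Stages
    with fewer than two usable samples are skipped from testing.
    """
    genes = sorted(set(candidates))
    if not genes:
        return pd.DataFrame(columns=["gene", "pattern"])
    sample_means: dict[str, np.ndarray] = {}
    for sample, cells in malignant_cells_by_sample.items():
        cells = np.asarray(cells, dtype=object)
        if len(cells) == 0:
            continue
        sample_means[sample] = matrix.normalized_dense(
            genes=np.asarray(genes, dtype=object), cells=cells).mean(axis=1)

    stage_samples = {
        s: [smp for smp, st in sample_stages.items()
            if st == s and smp in sample_means]
        for s in DISEASE_STAGES
    }
    rows = []
    pairs = list(combinations(DISEASE_STAGES, 2))
    for gi, gene in enumerate(genes):
        means, ses = {}, {}
        vals: dict[str, np.ndarray] = {}
        for stage in DISEASE_STAGES:
            v = np.array([sample_means[s][gi] for s in stage_samples[stage]])
            vals[stage] = v
            means[stage] = float(v.mean()) if len(v) else np.nan
            ses[stage] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        pvals = {}
        for a, b in pairs:
            if len(vals[a]) < 2 or len(vals[b]) < 2:
                logger.info("programs.temporal_classify: skipping %s vs %s for "
                            "%s (too few samples)", a, b, gene)
                continue
            if np.ptp(vals[a]) == 0 and np.ptp(vals[b]) == 0:
                pvals[(a, b)] = 1.0 if vals[a][0] == vals[b][0] else 0.0
                continue
            pvals[(a, b)] = float(stats.ttest_ind(vals[a], vals[b]).pvalue)
        n_tests = len(pvals)
        adj = {k: min(v * n_tests, 1.0) for k, v in pvals.items()}
        sig = {k: v < alpha for k, v in adj.items()}
        if not any(sig.values()):
            continue
        row = {"gene": gene, "pattern": _pattern(means, sig)}
        for stage in DISEASE_STAGES:
            row[f"mean_{stage}"] = means[stage]
            row[f"se_{stage}"] = ses[stage]
        for (a, b), v in adj.items():
            row[f"padj_{a}_vs_{b}"] = v
        rows.append(row)
    out = pd.DataFrame(rows)
    logger.info("programs.temporal_classify: %d / %d candidates retained",
                len(out), len(genes))
    return out


def cluster_programs(
    per_cluster_markers: dict[str, list[str]],
    gene_sets: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
    cut_height: float = 0.7,
) -> ProgramSimilarity:
    """Group per-sample clusters by the Jaccard similarity of their enriched
    term sets.

    ``per_cluster_markers`` maps "sample:cluster" keys to marker gene lists.
    Clusters without any significantly enriched term (hypergeometric,
    BH-FDR < ``alpha``) are excluded with a log line. The remaining clusters
    are grouped by complete-linkage hierarchical clustering on 1 - Jaccard,
    cut at ``cut_height``; singleton groups are the divergent clusters.
    """
    term_sets: dict[str, set[str]] = {}
    for key in sorted(per_cluster_markers):
        markers = [g for g in per_cluster_markers[key] if g in set(universe)]
        if not markers:
            logger.info("programs.cluster_programs: cluster %s has no usable "
                        "markers; excluded", key)
            continue
        enr = hypergeom_enrich(markers, universe, gene_sets, alpha=alpha)
        terms = set(enr.loc[enr["significant"], "term"])
        if terms:
            term_sets[key] = terms
        else:
            logger.info("programs.cluster_programs: cluster %s has no enriched "
                        "terms; excluded", key)
    keys = sorted(term_sets)
    if len(keys) < 2:
        raise ValueError("need at least 2 clusters with enriched terms")

    n = len(keys)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = term_sets[keys[i]], term_sets[keys[j]]
            J[i, j] = J[j, i] = len(a & b) / len(a | b)
    jaccard = pd.DataFrame(J, index=keys, columns=keys)

    dist = squareform(1.0 - J, checks=False)
    Z = linkage(dist, method="complete")
    groups = fcluster(Z, t=cut_height, criterion="distance")
    # stable program ids: letters by decreasing group size, then first member
    order = pd.Series(groups).value_counts().index
    name = {}
    multi = 0
    for g in order:
        members = [keys[i] for i in range(n) if groups[i] == g]
        if len(members) > 1:
            name[g] = chr(ord("A") + multi)
            multi += 1
    singles = 0
    for g in order:
        if g not in name:
            singles += 1
            name[g] = f"divergent_{singles}"
    assignments = pd.Series({keys[i]: name[groups[i]] for i in range(n)},
                            name="program")

    mean_within: dict[str, float] = {}
    for prog in sorted(set(assignments)):
        members = [k for k in keys if assignments[k] == prog]
        if len(members) > 1:
            idx = [keys.index(k) for k in members]
            vals = [J[i, j] for i, j in combinations(idx, 2)]
            mean_within[prog] = float(np.mean(vals))
    between = [J[i, j] for i, j in combinations(range(n), 2)
               if assignments[keys[i]] != assignments[keys[j]]]
    mean_between = float(np.mean(between)) if between else float("nan")
    logger.info("programs.cluster_programs: %d clusters -> programs %s; "
                "between-program mean J=%.3f",
                n, {k: f"{v:.3f}" for k, v in mean_within.items()}, mean_between)
    return ProgramSimilarity(keys, jaccard, assignments, mean_within,
                             mean_between, term_sets)


def cohort_association(
    malignant_fraction: pd.Series,
    mprotein: pd.Series,
    stage_labels: pd.Series,
) -> dict:
    """Cohort statistics: Pearson correlation (two-sided t-based p) between
    per-sample malignant fraction and M-protein, and all pairwise stage
    comparisons of M-protein (rank-sum, BH-corrected)."""
    idx = malignant_fraction.index
    x = malignant_fraction.to_numpy(dtype=float)
    y = mprotein.reindex(idx).to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r, p = float("nan"), float("nan")
        logger.warning("programs.cohort_association: constant vector; "
                       "correlation undefined")
    else:
        r, p = (float(v) for v in stats.pearsonr(x, y))
    stages = stage_labels.reindex(idx)
    rows = []
    for a, b in combinations(sorted(stages.unique()), 2):
        ya, yb = y[(stages == a).to_numpy()], y[(stages == b).to_numpy()]
        if len(ya) and len(yb):
            stat = stats.mannwhitneyu(ya, yb, alternative="two-sided",
                                      method="asymptotic")
            rows.append({"group_a": a, "group_b": b, "p": float(stat.pvalue)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy())
    return {"pearson_r": r, "pearson_p": p, "pairwise_mprotein": pairwise}
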