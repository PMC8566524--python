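"""End-to-end orchestration of the analysis stages from a single run
configuration, with a manifest recording parameters, seed, and output
digests so that reruns are verifiably bit-identical."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, cnv, embed_cluster, programs, score
from .diffexpr import DeParams, wilcoxon_de
from .io_formats import write_counts, write_gene_annotation, write_gmt
from .preprocess import (QcThresholds, cell_qc_metrics, filter_genes,
                         lognormalize, qc_filter_cells, scale_regress,
                         select_hvg)
from .simulate import SimConfig, make_reference_profiles, simulate_cohort

logger = logging.getLogger("mmprog")

STAGE_ORDER = ("simulate", "qc", "cluster", "annotate", "score", "programs", "cnv")
STAGE_DEPS = {
    "qc": ("simulate",),
    "cluster": ("qc",),
    "annotate": ("cluster",),
    "score": ("annotate",),
    "programs": ("annotate",),
    "cnv": ("annotate",),
}
_KNOWN_KEYS = {"seed", "stages", "simulate", "qc", "cluster", "out"}


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_hvg: int = 3000
    n_pcs: int = 50

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        seed = int(raw.get("seed", 0))
        stages = tuple(raw.get("stages", STAGE_ORDER))
        for s in stages:
            if s not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
        sim_over = dict(raw.get("simulate", {}))
        sim_over.setdefault("seed", seed)
        bad = set(sim_over) - set(SimConfig.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown simulate key(s): {sorted(bad)}")
        qc_over = dict(raw.get("qc", {}))
        bad = set(qc_over) - set(QcThresholds.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown qc key(s): {sorted(bad)}")
        cl = dict(raw.get("cluster", {}))
        bad = set(cl) - {"n_hvg", "n_pcs"}
        if bad:
            raise ValueError(f"unknown cluster key(s): {sorted(bad)}")
        cfg = cls(seed=seed, stages=stages, sim=SimConfig(**sim_over),
                  qc=QcThresholds(**qc_over))
        cfg.n_hvg = int(cl.get("n_hvg", 3000))
        cfg.n_pcs = int(cl.get("n_pcs", 50))
        return cfg

    def check_dependencies(self) -> None:
        enabled = set(self.stages)
        for s in enabled:
            for dep in STAGE_DEPS.get(s, ()):
                if dep not in enabled:
                    raise ValueError(f"stage {s!r} requires stage {dep!r}")


def _write_tsv(df: pd.DataFrame, path: Path, outputs: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages; write all tables plus a manifest under
    ``out_dir`` and return the manifest dict."""
    config.check_dependencies()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    enabled = set(config.stages)
    seed = config.seed

    # --- simulate -----------------------------------------------------------
    matrix, cell_table, annotation_df, truth = simulate_cohort(config.sim)
    if "simulate" in enabled:
        write_counts(matrix, out / "counts.mtx", out / "genes.tsv",
                     out / "barcodes.tsv")
        for f in ("counts.mtx", "genes.tsv", "barcodes.tsv"):
            outputs[f] = hashlib.sha256((out / f).read_bytes()).hexdigest()
        _write_tsv(cell_table, out / "cell_table.tsv", outputs)
        write_gene_annotation(annotation_df, out / "gene_annotation.tsv")
        outputs["gene_annotation.tsv"] = hashlib.sha256(
            (out / "gene_annotation.tsv").read_bytes()).hexdigest()
        write_gmt(truth.gene_sets, out / "signatures.gmt")
        write_gmt(truth.enrichment_sets, out / "terms.gmt")
        _write_tsv(truth.samples, out / "samples.tsv", outputs)
        _write_tsv(truth.cells, out / "truth_cells.tsv", outputs)

    results: dict = {"seed": seed}
    if "qc" not in enabled:
        return _finish(out, config, outputs, results)

    # --- qc / preprocess ----------------------------------------------------
    filtered, qc_report = qc_filter_cells(matrix, annotation_df, config.qc)
    sample_of = cell_table.set_index("cell_id")["sample"]
    stage_of = cell_table.set_index("cell_id")["stage"]
    filtered = filter_genes(filtered, sample_of.reindex(filtered.cell_ids),
                            config.qc)
    lognormalize(filtered)
    _write_tsv(qc_report, out / "qc_report.tsv", outputs)
    metrics = cell_qc_metrics(filtered, annotation_df).set_index("cell_id")
    pct_mito = metrics["pct_mito"].reindex(filtered.cell_ids).to_numpy()
    hvg = select_hvg(filtered, n=min(config.n_hvg, filtered.n_genes))
    scale_regress(filtered, hvg, pct_mito)
    results["n_cells_pass_qc"] = filtered.n_cells
    results["n_genes_pass_filter"] = filtered.n_genes

    if "cluster" not in enabled:
        return _finish(out, config, outputs, results)

    # --- lineage-level clustering -------------------------------------------
    emb = embed_cluster.pca(filtered, n_components=config.n_pcs)
    k_pcs = embed_cluster.select_pcs_knee(emb.explained_variance)
    lineage_clust = embed_cluster.optimize_resolution(
        filtered, emb, k_pcs,
        resolutions=embed_cluster.LINEAGE_RESOLUTIONS,
        min_de_genes=embed_cluster.LINEAGE_MIN_DE_GENES,
        seed=seed,
    )
    clusters = pd.DataFrame({"cell_id": filtered.cell_ids,
                             "cluster": lineage_clust.labels})
    _write_tsv(clusters, out / "clusters.tsv", outputs)
    _write_tsv(lineage_clust.scan, out / "resolution_scan.tsv", outputs)
    results["k_pcs"] = int(k_pcs)
    results["lineage_resolution"] = lineage_clust.resolution
    results["n_lineage_clusters"] = int(len(np.unique(lineage_clust.labels)))

    if "annotate" not in enabled:
        return _finish(out, config, outputs, results)

    # --- lineage annotation and malignant split ------------------------------
    profiles = make_reference_profiles(truth, matrix)
    calls = annotate.correlation_classify(filtered, profiles)
    cluster_anno = annotate.majority_annotate_clusters(
        calls, lineage_clust.labels, target_labels={"B", "PC"})
    b_pc_clusters = set(cluster_anno.index[cluster_anno == "B_PC"])
    in_b_pc = np.isin(lineage_clust.labels, list(b_pc_clusters))
    b_cells = filtered.cell_ids[in_b_pc]

    plasma_scores_all = score.module_score(
        filtered, truth.gene_sets["plasma_signature"],
        score.ModuleScoreParams(seed=seed))
    plasma_flags = annotate.call_plasma_cells(
        filtered, b_cells, lineage_clust.labels[in_b_pc],
        plasma_scores_all[in_b_pc])
    plasma_cells = plasma_flags.index[plasma_flags].to_numpy()
    split = annotate.split_malignant(
        filtered, plasma_cells, "tMYC",
        sample_stages=stage_of, seed=seed)
    anno_table = pd.DataFrame({
        "cell_id": filtered.cell_ids,
        "lineage": calls["best_label"].to_numpy(),
        "cluster": lineage_clust.labels,
        "cluster_annotation": [cluster_anno[c] for c in lineage_clust.labels],
        "plasma_score": plasma_scores_all,
    })
    anno_table["is_plasma"] = anno_table["cell_id"].isin(set(plasma_cells))
    mal_set = set(split.loc[split["is_malignant"], "cell_id"])
    anno_table["is_malignant"] = anno_table["cell_id"].isin(mal_set)
    _write_tsv(anno_table, out / "annotation.tsv", outputs)
    results["n_plasma"] = int(anno_table["is_plasma"].sum())
    results["n_malignant"] = int(anno_table["is_malignant"].sum())

    if "score" in enabled:
        cc = score.assign_cell_cycle(
            filtered, truth.gene_sets["s_genes"], truth.gene_sets["g2m_genes"],
            score.ModuleScoreParams(seed=seed))
        _write_tsv(cc, out / "cell_cycle.tsv", outputs)

    mal_table = anno_table[anno_table["is_malignant"]]
    normal_pc = anno_table.loc[anno_table["is_plasma"]
                               & ~anno_table["is_malignant"], "cell_id"].to_numpy()
    stage_per_cell = stage_of.reindex(anno_table["cell_id"]).to_numpy()
    sample_per_cell = sample_of.reindex(anno_table["cell_id"]).to_numpy()

    if "programs" in enabled:
        _run_programs(config, filtered, truth, anno_table, stage_per_cell,
                      sample_per_cell, normal_pc, out, outputs, results, seed)
    if "cnv" in enabled:
        _run_cnv(filtered, annotation_df, anno_table, sample_per_cell,
                 normal_pc, out, outputs, results, seed)
    return _finish(out, config, outputs, results)


def _cluster_malignant_per_sample(filtered, anno_table, sample_per_cell, seed):
    """Resolution-optimized sub-clustering of each active sample's malignant
    cells; returns {sample: (cell_ids, labels)}."""
    out = {}
    mal_mask = anno_table["is_malignant"].to_numpy()
    for sample in pd.unique(sample_per_cell):
        cells = anno_table.loc[mal_mask & (sample_per_cell == sample),
                               "cell_id"].to_numpy()
        if len(cells) < 50:
            continue
        labels = annotate._subcluster(filtered, cells, seed=seed)
        out[str(sample)] = (cells, labels)
    return out


def _run_programs(config, filtered, truth, anno_table, stage_per_cell,
                  sample_per_cell, normal_pc, out, outputs, results, seed):
    mal_mask = anno_table["is_malignant"].to_numpy()
    mal_by_stage = {
        s: anno_table.loc[mal_mask & (stage_per_cell == s), "cell_id"].to_numpy()
        for s in programs.DISEASE_STAGES
    }
    if all(len(v) >= 20 for v in mal_by_stage.values()) and len(normal_pc) >= 20:
        core = programs.core_program(filtered, mal_by_stage, normal_pc)
        write_gmt({"core_up": core.up_genes or {"none"},
                   "core_down": core.down_genes or {"none"}},
                  out / "core_program.gmt")
        results["core_up_genes"] = sorted(core.up_genes)
        results["core_down_genes"] = sorted(core.down_genes)

        mal_by_sample = {}
        sample_stage = {}
        for sample in pd.unique(sample_per_cell):
            st = truth.samples.set_index("sample")["stage"].get(str(sample))
            if st in programs.DISEASE_STAGES:
                sample_stage[str(sample)] = st
                mal_by_sample[str(sample)] = anno_table.loc[
                    mal_mask & (sample_per_cell == sample), "cell_id"].to_numpy()
        candidates = programs.stage_specific_candidates(
            filtered, mal_by_sample, sample_stage)
        all_cand = set().union(*candidates.values())
        temporal = programs.temporal_classify(
            filtered, all_cand, mal_by_sample, sample_stage)
        _write_tsv(temporal if len(temporal) else
                   pd.DataFrame(columns=["gene", "pattern"]),
                   out / "temporal_genes.tsv", outputs)
        results["n_temporal_genes"] = int(len(temporal))

    # per-active-sample malignant clusters -> markers -> similarity programs
    sub = _cluster_malignant_per_sample(filtered, anno_table, sample_per_cell, seed)
    markers = {}
    for sample, (cells, labels) in sub.items():
        if len(np.unique(labels)) < 2:
            logger.info("pipeline: sample %s has a single malignant cluster; "
                        "no markers", sample)
            continue
        for c in np.unique(labels):
            de = wilcoxon_de(filtered, cells[labels == c], cells[labels != c],
                             DeParams.markers())
            up = de.loc[de["significant"] & (de["logfc"] > 0), "gene"].tolist()
            if up:
                markers[f"{sample}:{c}"] = up
    results["n_marker_clusters"] = len(markers)
    if len(markers) >= 2:
        try:
            sim = programs.cluster_programs(markers, truth.enrichment_sets,
                                            filtered.gene_ids)
            sim.jaccard.to_csv(out / "jaccard.tsv", sep="\t")
            outputs["jaccard.tsv"] = hashlib.sha256(
                (out / "jaccard.tsv").read_bytes()).hexdigest()
            _write_tsv(sim.assignments.rename_axis("cluster").reset_index(),
                       out / "program_assignments.tsv", outputs)
            results["mean_within_program_jaccard"] = sim.mean_within
            results["mean_between_program_jaccard"] = sim.mean_between
        except ValueError as exc:
            logger.warning("pipeline: similarity programs skipped: %s", exc)

    # cohort association of malignant fraction with the M-protein surrogate
    per_sample = pd.Series(sample_per_cell).value_counts()
    mal_frac = (pd.Series(sample_per_cell[mal_mask]).value_counts()
                .reindex(per_sample.index).fillna(0) / per_sample)
    mp = truth.samples.set_index("sample")["mprotein"].reindex(mal_frac.index)
    stages = truth.samples.set_index("sample")["stage"].reindex(mal_frac.index)
    assoc = programs.cohort_association(mal_frac, mp, stages)
    results["malignant_fraction_mprotein_r"] = assoc["pearson_r"]
    results["malignant_fraction_mprotein_p"] = assoc["pearson_p"]
    _write_tsv(assoc["pairwise_mprotein"], out / "stage_mprotein_tests.tsv",
               outputs)


def _run_cnv(filtered, annotation_df, anno_table, sample_per_cell, normal_pc,
             out, outputs, results, seed):
    if len(normal_pc) < 20:
        logger.warning("pipeline: too few normal plasma cells for CNV reference")
        return
    mal_mask = anno_table["is_malignant"].to_numpy()
    sub = _cluster_malignant_per_sample(filtered, anno_table, sample_per_cell,
                                        seed)
    label_rows = []
    state_tables, comp_tables = [], []
    n_subpops, n_clusters = [], []
    for sample, (cells, labels) in sub.items():
        profile = cnv.infer_cnv_matrix(filtered, annotation_df, cells, normal_pc)
        subpops = cnv.partition_subpopulations(profile)
        states = cnv.call_states(profile)
        states.insert(0, "sample", sample)
        state_tables.append(states[states["state"] != "neutral"])
        _, comp = cnv.map_subpops_to_clusters(
            pd.Series(subpops, index=cells), pd.Series(labels, index=cells))
        comp.insert(0, "sample", sample)
        comp_tables.append(comp)
        for cid, sp_, cl in zip(cells, subpops, labels):
            label_rows.append({"cell_id": cid, "sample": sample,
                               "subpop": int(sp_), "cluster": int(cl)})
        n_subpops.append(len(np.unique(subpops)))
        n_clusters.append(len(np.unique(labels)))
    if state_tables:
        _write_tsv(pd.concat(state_tables, ignore_index=True),
                   out / "cnv_states.tsv", outputs)
        _write_tsv(pd.concat(comp_tables, ignore_index=True),
                   out / "cnv_composition.tsv", outputs)
    if label_rows:
        _write_tsv(pd.DataFrame(label_rows), out / "cnv_subpopulations.tsv",
                   outputs)
        r, p = cnv.subpop_cluster_count_correlation(
            np.array(n_subpops), np.array(n_clusters))
        results["n_cnv_subpops_per_sample"] = n_subpops
        results["n_tx_clusters_per_sample"] = n_clusters
        results["subpop_cluster_count_r"] = r
        results["subpop_cluster_count_p"] = p


def _finish(out: Path, config: RunConfig, outputs: dict, results: dict) -> dict:
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {"sim": asdict(config.sim), "qc": asdict(config.qc),
                       "n_hvg": config.n_hvg, "n_pcs": config.n_pcs},
        "outputs": outputs,
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str, sort_keys=True))
    logger.info("pipeline: wrote %d outputs to %s", len(outputs), out)
    return manifest
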