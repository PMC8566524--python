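import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mmprog import cnv
from mmprog.preprocess import filter_genes, lognormalize, qc_filter_cells
from mmprog.simulate import CnvBlockSpec, SimConfig, simulate_cohort


def cnv_config(seed, **over):
    """Cohort isolating the copy-number signal: three subclones with
    disjoint 150-gene whole-arm-scale blocks, no co-planted programs."""
    base = dict(
        seed=seed,
        n_samples_per_stage={s: 1 for s in
                             ("control", "early", "intermediate", "active")},
        cells_per_sample=1200, n_chromosomes=10,
        malignant_fraction_jitter=0.0,
        lineage_fractions={
            s: ({"B": 0.2, "PC": 0.7, "other": 0.1} if s == "active"
                else {"B": 0.5, "PC": 0.06, "other": 0.44})
            for s in ("control", "early", "intermediate", "active")},
        cnv_blocks=[CnvBlockSpec("chr3", 10, 160, 0.5, ("s1",)),
                    CnvBlockSpec("chr5", 20, 170, 0.5, ("s2",)),
                    CnvBlockSpec("chr7", 30, 180, 1.5, ("s3",))],
        subclone_proportions={"s1": 1 / 3, "s2": 1 / 3, "s3": 1 / 3},
        program_definitions=[], divergent_program_fraction=0.0, cc_fold=1.0)
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="module")
def cnv_cohort():
    matrix, cell_table, annotation, truth = simulate_cohort(cnv_config(1))
    m, _ = qc_filter_cells(matrix, annotation)
    m = filter_genes(m, cell_table.set_index("cell_id")["sample"]
                     .reindex(m.cell_ids))
    lognormalize(m)
    tc = truth.cells.set_index("cell_id").reindex(m.cell_ids)
    normal_pc = tc.index[(tc["lineage"] == "PC") & ~tc["malignant"]
                         & ~tc["low_quality"]].to_numpy()
    malignant = tc.index[tc["malignant"]].to_numpy()
    profile = cnv.infer_cnv_matrix(m, annotation, malignant, normal_pc)
    return {"matrix": m, "annotation": annotation, "truth": truth,
            "truth_cells": tc, "normal_pc": normal_pc,
            "malignant": malignant, "profile": profile}


class TestInferCnvMatrix:
    def test_planted_deletion_visible_in_carriers_only(self, cnv_cohort):
        prof = cnv_cohort["profile"]
        truth, tc = cnv_cohort["truth"], cnv_cohort["truth_cells"]
        block = set(truth.cnv_blocks.query("chromosome == 'chr5'")
                    .iloc[0]["genes"])
        in_block = np.isin(prof.ordered_genes, list(block))
        carrier = (tc.loc[cnv_cohort["malignant"], "subclone"] == "s2").to_numpy()
        assert prof.smoothed[np.ix_(carrier, in_block)].mean() < -0.2
        assert abs(prof.smoothed[np.ix_(carrier, ~in_block)].mean()) < 0.05
        assert abs(prof.smoothed[np.ix_(~carrier, in_block)].mean()) < 0.05

    def test_null_observations_mostly_zero_after_denoising(self, cnv_cohort):
        npc = cnv_cohort["normal_pc"]
        half = len(npc) // 2
        prof = cnv.infer_cnv_matrix(cnv_cohort["matrix"],
                                    cnv_cohort["annotation"],
                                    npc[:half], npc[half:])
        assert (prof.smoothed == 0).mean() >= 0.95

    def test_identity_window_without_denoise_or_clamp(self):
        """window=1, denoise off, huge clamp: smoothing reduces to the
        centered per-gene values (up to per-cell median re-centering)."""
        rng = np.random.default_rng(0)
        from .conftest import make_matrix
        counts = rng.poisson(3.0, size=(40, 60))
        m = make_matrix(counts)
        lognormalize(m)
        ann = pd.DataFrame({"gene_id": m.gene_ids, "chromosome": "chr1",
                            "start": np.arange(40) * 10, "is_mito": False})
        obs, ref = m.cell_ids[:30], m.cell_ids[30:]
        prof = cnv.infer_cnv_matrix(m, ann, obs, ref, window=1,
                                    denoise=False, max_centered=1e9)
        totals = np.asarray(m.counts.sum(axis=0)).ravel()
        expr = np.log2(np.asarray(m.counts.todense()) / totals * 10000 + 1)
        order = m.gene_indexer(prof.ordered_genes)
        centered = (expr[order] - expr[order][:, 30:].mean(axis=1,
                                                           keepdims=True)).T
        centered = centered[:30]
        centered -= np.median(centered, axis=1, keepdims=True)
        np.testing.assert_allclose(prof.smoothed, centered, atol=1e-10)

    def test_smoothing_linearity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 200))
        a = cnv._smooth_centered(X, np.array(["c1"] * 200, dtype=object), 21)
        b = cnv._smooth_centered(3.0 * X, np.array(["c1"] * 200, dtype=object),
                                 21)
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-12)

    def test_no_reference_cells_rejected(self, cnv_cohort):
        with pytest.raises(ValueError, match="no reference"):
            cnv.infer_cnv_matrix(cnv_cohort["matrix"],
                                 cnv_cohort["annotation"],
                                 cnv_cohort["malignant"], [])


class TestPartitionSubpopulations:
    def test_three_planted_subclones_recovered(self, cnv_cohort):
        labels = cnv.partition_subpopulations(cnv_cohort["profile"])
        truth = cnv_cohort["truth_cells"].loc[cnv_cohort["malignant"],
                                              "subclone"]
        assert len(np.unique(labels)) == 3
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_null_data_yields_single_subpopulation(self, cnv_cohort):
        npc = cnv_cohort["normal_pc"]
        half = len(npc) // 2
        prof = cnv.infer_cnv_matrix(cnv_cohort["matrix"],
                                    cnv_cohort["annotation"],
                                    npc[:half], npc[half:])
        labels = cnv.partition_subpopulations(prof)
        assert len(np.unique(labels)) == 1

    def test_invariant_to_cell_order(self, cnv_cohort):
        prof = cnv_cohort["profile"]
        labels = cnv.partition_subpopulations(prof)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(prof.cell_ids))
        import copy
        prof2 = copy.deepcopy(prof)
        prof2.smoothed = prof.smoothed[perm]
        prof2.smoothed_raw = prof.smoothed_raw[perm]
        prof2.cell_ids = prof.cell_ids[perm]
        labels2 = cnv.partition_subpopulations(prof2)
        assert adjusted_rand_score(labels[perm], labels2) == 1.0


class TestCallStates:
    def test_planted_deletion_called_as_loss(self, cnv_cohort):
        prof = cnv_cohort["profile"]
        labels = cnv.partition_subpopulations(prof)
        states = cnv.call_states(prof)
        truth, tc = cnv_cohort["truth"], cnv_cohort["truth_cells"]
        sub = tc.loc[cnv_cohort["malignant"], "subclone"]
        block = sorted(set(truth.cnv_blocks.query("chromosome == 'chr5'")
                           .iloc[0]["genes"]) & set(prof.ordered_genes))
        for sp in np.unique(labels):
            majority = sub[labels == sp].mode()[0]
            st = states[states["subpop"] == sp].set_index("gene")["state"]
            coverage = (st.loc[block] == "loss").mean()
            if majority == "s2":
                assert coverage >= 0.8
            else:
                assert coverage <= 0.05

    def test_far_from_blocks_almost_all_neutral(self, cnv_cohort):
        """Miscalls are confined to the smoothing window's reach around true
        blocks; genes farther away are neutral in > 99% of calls."""
        prof = cnv_cohort["profile"]
        cnv.partition_subpopulations(prof)
        states = cnv.call_states(prof)
        truth = cnv_cohort["truth"]
        block_genes = set().union(*[set(g) for g in truth.cnv_blocks["genes"]])
        pos = {g: i for i, g in enumerate(prof.ordered_genes)}
        bp = np.array(sorted(pos[g] for g in block_genes if g in pos))
        gene_pos = np.array([pos[g] for g in states["gene"]])
        dist = np.abs(gene_pos[:, None] - bp[None, :]).min(axis=1)
        far = states[dist > 51]
        assert (far["state"] != "neutral").mean() < 0.01

    def test_all_zero_profile_all_neutral(self):
        prof = cnv.CnvProfile(
            cell_ids=np.array(["c1", "c2"], dtype=object),
            ordered_genes=np.array([f"g{i}" for i in range(50)], dtype=object),
            chromosomes=np.array(["chr1"] * 50, dtype=object),
            smoothed=np.zeros((2, 50)), reference_sd=0.1)
        states = cnv.call_states(prof, subpop_labels=np.zeros(2, int))
        assert (states["state"] == "neutral").all()

    def test_short_dip_below_min_run_stays_neutral(self):
        smoothed = np.zeros((3, 60))
        smoothed[:, 20:30] = -0.5  # 10-gene dip < min_run of 20
        prof = cnv.CnvProfile(
            cell_ids=np.array(["a", "b", "c"], dtype=object),
            ordered_genes=np.array([f"g{i}" for i in range(60)], dtype=object),
            chromosomes=np.array(["chr1"] * 60, dtype=object),
            smoothed=smoothed, reference_sd=0.1)
        states = cnv.call_states(prof, subpop_labels=np.zeros(3, int))
        assert (states["state"] == "neutral").all()


class TestMapSubpopsToClusters:
    def test_contingency_margins(self):
        idx = [f"c{i}" for i in range(60)]
        sub = pd.Series(np.repeat([0, 1, 2], 20), index=idx)
        clu = pd.Series(np.tile([0, 1], 30), index=idx)
        table, summary = cnv.map_subpops_to_clusters(sub, clu)
        assert table.to_numpy().sum(axis=1).tolist() == [20, 20, 20]
        assert table.to_numpy().sum(axis=0).tolist() == [30, 30]

    def test_identical_labelings_majority_one(self):
        idx = [f"c{i}" for i in range(40)]
        lab = pd.Series(np.repeat([0, 1], 20), index=idx)
        _, summary = cnv.map_subpops_to_clusters(lab, lab.copy())
        assert (summary["majority_fraction"] == 1.0).all()

    def test_uniform_split_majority_quarter(self):
        idx = [f"c{i}" for i in range(400)]
        sub = pd.Series(np.zeros(400, int), index=idx)
        clu = pd.Series(np.tile([0, 1, 2, 3], 100), index=idx)
        _, summary = cnv.map_subpops_to_clusters(sub, clu)
        subpop_rows = summary[summary["axis"] == "subpop"]
        np.testing.assert_allclose(subpop_rows["majority_fraction"], 0.25)
        cluster_rows = summary[summary["axis"] == "cluster"]
        np.testing.assert_allclose(cluster_rows["majority_fraction"], 1.0)

    def test_mismatched_universe_rejected(self):
        a = pd.Series([0, 1], index=["c1", "c2"])
        b = pd.Series([0, 1], index=["c1", "c3"])
        with pytest.raises(ValueError, match="different cells"):
            cnv.map_subpops_to_clusters(a, b)

    def test_independent_counts_usually_not_significant(self):
        """Independently drawn per-sample subpopulation and cluster counts
        yield a non-significant correlation in >= 90% of replicates."""
        rng = np.random.default_rng(0)
        nonsig = 0
        n_rep = 50
        for _ in range(n_rep):
            ns = rng.integers(1, 9, size=7)
            nc = rng.integers(2, 14, size=7)
            r, p = cnv.subpop_cluster_count_correlation(ns, nc)
            if np.isnan(p) or p > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_rep


class TestSubpopMarkerAnalysis:
    def test_planted_program_recovered_in_deletion_carriers(self):
        cfg = cnv_config(3)
        from mmprog.simulate import ProgramSpec
        # deletion carriers (s2) also carry a 3-fold program in all cells
        cfg.program_definitions = []
        matrix, cell_table, annotation, truth = simulate_cohort(cfg)
        m, _ = qc_filter_cells(matrix, annotation)
        m = filter_genes(m, cell_table.set_index("cell_id")["sample"]
                         .reindex(m.cell_ids))
        lognormalize(m)
        tc = truth.cells.set_index("cell_id").reindex(m.cell_ids)
        carriers = tc.index[tc["malignant"] & (tc["subclone"] == "s2")].to_numpy()
        others = tc.index[tc["malignant"] & (tc["subclone"] != "s2")].to_numpy()
        de, enrich = cnv.subpop_marker_analysis(
            m, carriers, others, truth.enrichment_sets)
        # dosage-only carriers: every strong marker is a block gene (down)
        block = set(truth.cnv_blocks.query("chromosome == 'chr5'")
                    .iloc[0]["genes"]) | \
            set(truth.cnv_blocks.query("chromosome == 'chr3'").iloc[0]["genes"]) | \
            set(truth.cnv_blocks.query("chromosome == 'chr7'").iloc[0]["genes"])
        sig = de[de["significant"]]
        assert len(sig) > 0
        assert set(sig["gene"]) <= block

    def test_empty_carrier_set_rejected(self, cnv_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            cnv.subpop_marker_analysis(cnv_cohort["matrix"], [],
                                       cnv_cohort["malignant"], {})
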