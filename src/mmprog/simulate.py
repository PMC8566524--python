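"""Synthetic multi-sample cohort generator.

Emulates a longitudinal bone-marrow single-cell cohort from a transgenic
myeloma model: samples span four disease-stage groups (control, early,
intermediate, active); cells belong to B, plasma (PC), or other lineages;
malignant cells are plasma cells expressing an oncogenic transgene and carry
planted structure the analysis modules are designed to recover — contiguous
CNV blocks private to subclones, a core malignant expression program shared
across stages, stage-specific temporal genes, shared and sample-private
subclonal programs, cell-cycle signatures, mitochondrial content, and a
handful of deliberately low-quality cells.

Counts are negative binomial with a shared dispersion; every planted effect
acts multiplicatively on the gene mean. A per-sample M-protein surrogate (a
logistic function of the true malignant fraction plus Gaussian noise) gives
cohort-level association analyses a planted correlation to recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ExpressionMatrix
from .preprocess import lognormalize

logger = logging.getLogger("mmprog")

STAGES = ("control", "early", "intermediate", "active")
STAGE_PREFIX = {"control": "Cont", "early": "EMM",
                "intermediate": "IMM", "active": "AMM"}
TRANSGENE = "tMYC"


@dataclass
class CnvBlockSpec:
    """Contiguous dosage alteration: ``dosage`` multiplies the mean of genes
    ``start..end`` (0-based, end exclusive, indices within the chromosome)
    in cells of the carrier subclones."""
    chromosome: str
    start: int
    end: int
    dosage: float
    carriers: tuple[str, ...]


@dataclass
class ProgramSpec:
    """Transcriptional program: ``n_genes`` genes upregulated ``fold``-fold in
    a ``carrier_fraction`` of each sample's malignant cells. Shared programs
    recur in every active sample; private ones in a single sample."""
    name: str
    n_genes: int = 40
    fold: float = 3.0
    carrier_fraction: float = 0.25
    shared: bool = True


@dataclass
class TemporalSpec:
    """One gene whose malignant-cell expression follows a per-stage fold
    profile (early, intermediate, active)."""
    name: str
    profile: tuple[float, float, float]


def _default_programs() -> list[ProgramSpec]:
    return [
        ProgramSpec("progA", 40, 3.0, 0.25, shared=True),
        ProgramSpec("progB", 40, 3.0, 0.25, shared=True),
    ]


def _default_blocks() -> list[CnvBlockSpec]:
    """Whole-chromosome dosage events, several per subclone, with partial
    sharing (a truncal gain plus branch-private events) — the arm-scale
    aneuploidy pattern typical of plasma-cell neoplasms."""
    return [
        CnvBlockSpec("chr2", 0, 99, 1.5, ("s1", "s3")),
        CnvBlockSpec("chr7", 0, 99, 0.5, ("s1",)),
        CnvBlockSpec("chr5", 0, 99, 0.5, ("s2", "s3")),
        CnvBlockSpec("chr11", 0, 99, 1.5, ("s2",)),
        CnvBlockSpec("chr13", 0, 99, 0.5, ("s3",)),
    ]


def _default_temporal() -> list[TemporalSpec]:
    return [
        TemporalSpec("tmp-dec-1", (3.0, 2.0, 1.0)),
        TemporalSpec("tmp-dec-2", (3.0, 2.0, 1.0)),
        TemporalSpec("tmp-early-1", (3.0, 0.7, 1.0)),
        TemporalSpec("tmp-early-2", (3.0, 0.7, 1.0)),
        TemporalSpec("tmp-int-1", (1.0, 3.0, 1.0)),
        TemporalSpec("tmp-int-2", (1.0, 3.0, 1.0)),
    ]


@dataclass
class SimConfig:
    """Cohort design. The defaults define the package's reference cohort:
    12 samples (3 per stage) of 800 cells over 2,000 genes on 19 autosomes
    plus X (10 genes/Mb), with every planted structure at recoverable but
    not caricatural effect sizes."""

    n_samples_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 3 for s in STAGES})
    cells_per_sample: int = 800
    n_genes: int = 2000
    n_chromosomes: int = 20  # chr1..chr19 + chrX
    baseline_mean_law: tuple[float, float] = (-0.5, 1.0)  # lognormal (loc, scale)
    dispersion: float = 2.0  # negative-binomial size
    size_factor_sd: float = 0.35
    lineage_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"B": 0.50, "PC": 0.06, "other": 0.44},
            "early": {"B": 0.50, "PC": 0.06, "other": 0.44},
            "intermediate": {"B": 0.50, "PC": 0.06, "other": 0.44},
            "active": {"B": 0.50, "PC": 0.136, "other": 0.364},
        })
    malignant_fraction_by_stage: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "early": 0.04,
                                 "intermediate": 0.08, "active": 0.55})
    malignant_fraction_jitter: float = 0.25  # lognormal sd across samples
    transgene_fold: float = 8.0
    cnv_blocks: list[CnvBlockSpec] = field(default_factory=_default_blocks)
    subclone_proportions: dict[str, float] = field(
        default_factory=lambda: {"s1": 0.40, "s2": 0.35, "s3": 0.25})
    program_definitions: list[ProgramSpec] = field(default_factory=_default_programs)
    divergent_program_fraction: float = 0.20  # one private program per active sample
    divergent_program_genes: int = 40
    temporal_genes: list[TemporalSpec] = field(default_factory=_default_temporal)
    n_lineage_markers: int = 50
    lineage_marker_fold: float = 4.0
    #: core malignant program, scaled to the cohort's gene-model size
    core_up_genes: int = 40
    core_up_fold: float = 2.5
    core_down_genes: int = 15
    core_down_fold: float = 0.4
    n_cc_genes: int = 30  # per S / G2M signature
    cc_fold: float = 3.0
    #: cycling is largely confined to the malignant compartment: healthy
    #: plasma cells are post-mitotic and the other lineages are mostly
    #: quiescent at steady state
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.70, "S": 0.15, "G2M": 0.15})
    healthy_phase_fractions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.92, "S": 0.04, "G2M": 0.04})
    pct_mito_law: tuple[float, float] = (2.0, 38.0)  # Beta(a, b), mean 5%
    n_mito_genes: int = 10
    n_lowquality_cells: int = 30
    mprotein_midpoint: float = 0.15
    mprotein_scale: float = 0.10
    mprotein_noise_sd: float = 0.05
    n_decoy_terms: int = 20  # uninformative gene sets in the term collection
    term_size: int = 10  # planted programs are split into terms of this size
    seed: int = 0

    def validate(self) -> None:
        for stage, n in self.n_samples_per_stage.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 1:
                raise ValueError(f"empty stage group {stage!r}")
        for stage, fr in self.lineage_fractions.items():
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"lineage fractions for {stage!r} do not sum to 1")
        if abs(sum(self.subclone_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subclone proportions do not sum to 1")
        for b in self.cnv_blocks:
            if b.dosage <= 0:
                raise ValueError(f"non-positive dosage in block on {b.chromosome}")
        if self.transgene_fold <= 1:
            raise ValueError("transgene_fold must exceed 1")


@dataclass
class GroundTruth:
    """Planted structure, aligned with the emitted matrix by construction."""
    cells: pd.DataFrame  # cell_id, sample, stage, lineage, malignant, subclone,
    #                      program, phase, low_quality, size_factor
    samples: pd.DataFrame  # sample, stage, malignant_fraction, mprotein
    gene_sets: dict[str, set[str]]  # named planted sets (core, programs, cc, ...)
    temporal: pd.DataFrame  # gene, fold_early, fold_intermediate, fold_active
    cnv_blocks: pd.DataFrame  # subclone, chromosome, genes (list), dosage
    enrichment_sets: dict[str, set[str]]  # term collection for enrichment tests
    program_terms: dict[str, set[str]]  # program name -> its term names


def _gene_model(config: SimConfig, rng: np.random.Generator):
    """Gene ids, annotation, baseline means, and planted gene assignments."""
    n_positional = config.n_genes - config.n_mito_genes - 1
    chrom_names = [f"chr{i}" for i in range(1, config.n_chromosomes)] + ["chrX"]
    sizes = np.full(config.n_chromosomes, n_positional // config.n_chromosomes)
    sizes[: n_positional % config.n_chromosomes] += 1

    gene_ids: list[str] = []
    chroms: list[str] = []
    starts: list[int] = []
    gidx = 0
    chrom_span: dict[str, tuple[int, int]] = {}
    for cname, size in zip(chrom_names, sizes):
        chrom_span[cname] = (gidx, gidx + int(size))
        for j in range(int(size)):
            gene_ids.append(f"g{gidx:04d}")
            chroms.append(cname)
            starts.append(j * 100_000)  # 10 genes per Mb
            gidx += 1
    mito_ids = [f"mt-Gene{i + 1}" for i in range(config.n_mito_genes)]
    for i, mid in enumerate(mito_ids):
        gene_ids.append(mid)
        chroms.append("chrM")
        starts.append(i * 1_000)
    gene_ids.append(TRANSGENE)
    chroms.append("chrTg")
    starts.append(0)

    annotation = pd.DataFrame({"gene_id": gene_ids, "chromosome": chroms,
                               "start": starts})
    annotation["is_mito"] = annotation["gene_id"].str.startswith("mt-")

    loc, sc = config.baseline_mean_law
    base = rng.lognormal(loc, sc, size=len(gene_ids))
    base = np.minimum(base, 50.0)  # cap pathological draws

    # genes inside CNV blocks (kept free of other planted effects)
    block_gene_idx: dict[int, np.ndarray] = {}
    blocked: set[int] = set()
    for bi, b in enumerate(config.cnv_blocks):
        if b.chromosome not in chrom_span:
            raise ValueError(f"block chromosome {b.chromosome!r} not in gene model")
        lo, hi = chrom_span[b.chromosome]
        if b.end > hi - lo or b.start < 0 or b.start >= b.end:
            raise ValueError(
                f"block {b.start}:{b.end} exceeds {b.chromosome} span of {hi - lo} genes")
        idx = np.arange(lo + b.start, lo + b.end)
        block_gene_idx[bi] = idx
        blocked.update(idx.tolist())

    free = np.array(sorted(set(range(n_positional)) - blocked))
    n_active = config.n_samples_per_stage.get("active", 0)
    need = (3 * config.n_lineage_markers
            + config.core_up_genes + config.core_down_genes
            + sum(p.n_genes for p in config.program_definitions)
            + n_active * config.divergent_program_genes
            + len(config.temporal_genes) + 2 * config.n_cc_genes)
    if need > len(free):
        raise ValueError(f"gene model too small: need {need} planted genes, "
                         f"have {len(free)} outside CNV blocks")
    picked = rng.choice(free, size=need, replace=False)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = picked[cursor:cursor + n]
        cursor += n
        return out

    assign: dict[str, np.ndarray] = {
        "B_markers": take(config.n_lineage_markers),
        "PC_markers": take(config.n_lineage_markers),
        "other_markers": take(config.n_lineage_markers),
        "core_up": take(config.core_up_genes),
        "core_down": take(config.core_down_genes),
        "s_genes": take(config.n_cc_genes),
        "g2m_genes": take(config.n_cc_genes),
    }
    for p in config.program_definitions:
        assign[f"program:{p.name}"] = take(p.n_genes)
    for i in range(n_active):
        assign[f"program:div{i + 1}"] = take(config.divergent_program_genes)
    for t in config.temporal_genes:
        assign[f"temporal:{t.name}"] = take(1)

    # canonical marker names and planted-gene baselines
    names = np.array(gene_ids, dtype=object)
    names[assign["B_markers"][0]] = "Cd19"
    names[assign["PC_markers"][0]] = "Sdc1"
    base[assign["B_markers"]] = 1.2
    base[assign["PC_markers"]] = 1.2
    base[assign["other_markers"]] = 1.2
    base[assign["core_up"]] = 1.0
    base[assign["core_down"]] = 1.5
    base[assign["s_genes"]] = 0.8
    base[assign["g2m_genes"]] = 0.8
    for key, idx in assign.items():
        if key.startswith("program:"):
            base[idx] = 0.8
        elif key.startswith("temporal:"):
            base[idx] = 0.3
    base[len(gene_ids) - 1] = 1.0  # transgene baseline (malignant only)
    annotation["gene_id"] = names
    return names, annotation, base, assign, block_gene_idx, mito_ids


def _sample_names(config: SimConfig) -> list[tuple[str, str]]:
    out = []
    for stage in STAGES:
        for i in range(config.n_samples_per_stage.get(stage, 0)):
            out.append((f"{STAGE_PREFIX[stage]}{i + 1}", stage))
    return out


def simulate_cohort(
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort.

    Returns ``(matrix, cell_table, gene_annotation, truth)`` where
    ``cell_table`` carries only pipeline-visible metadata (sample, stage) and
    ``truth`` the full planted structure. Bit-identical for a fixed seed.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, annotation, base, assign, block_gene_idx, mito_ids = _gene_model(config, rng)
    n_genes = len(names)
    mito_idx = np.array([i for i, g in enumerate(names) if g.startswith("mt-")])
    tg_idx = n_genes - 1
    nonmito = np.ones(n_genes, dtype=bool)
    nonmito[mito_idx] = False
    nonmito[tg_idx] = False

    subclones = sorted(config.subclone_proportions)
    sub_probs = np.array([config.subclone_proportions[s] for s in subclones])
    phases = sorted(config.phase_fractions)
    phase_probs = np.array([config.phase_fractions[p] for p in phases])
    healthy_phase_probs = np.array([config.healthy_phase_fractions[p]
                                    for p in phases])
    stage_pos = {"early": 0, "intermediate": 1, "active": 2}

    shared_programs = [p for p in config.program_definitions if p.shared]
    private_programs = [p for p in config.program_definitions if not p.shared]

    counts_blocks: list[sp.csr_matrix] = []
    cell_rows: list[dict] = []
    sample_rows: list[dict] = []
    samples = _sample_names(config)
    active_seen = 0

    for sample, stage in samples:
        n_cells = config.cells_per_sample
        base_frac = config.malignant_fraction_by_stage.get(stage, 0.0)
        if base_frac > 0:
            frac = float(np.clip(
                base_frac * np.exp(rng.normal(0.0, config.malignant_fraction_jitter)),
                0.0, 0.9))
        else:
            frac = 0.0
        n_mal = int(round(frac * n_cells))
        lf = config.lineage_fractions[stage]
        lineages = sorted(lf)
        n_rest = n_cells - n_mal
        rest_counts = rng.multinomial(n_rest, np.array([lf[l] for l in lineages])
                                      / sum(lf.values()))
        lineage_per_cell = (["PC"] * n_mal
                            + sum(([l] * c for l, c in zip(lineages, rest_counts)), []))
        malignant = np.array([i < n_mal for i in range(n_cells)])

        # sample-level program menu (active samples get one private program)
        menu: list[tuple[str, float, float]] = [
            (p.name, p.fold, p.carrier_fraction) for p in shared_programs
        ]
        for p in private_programs:
            menu.append((p.name, p.fold, p.carrier_fraction))
        if stage == "active":
            active_seen += 1
            menu.append((f"div{active_seen}", 3.0, config.divergent_program_fraction))

        sub_assign = np.array(
            [subclones[i] for i in rng.choice(len(subclones), size=n_cells,
                                              p=sub_probs)], dtype=object)
        sub_assign[~malignant] = ""
        prog_assign = np.array([""] * n_cells, dtype=object)
        if n_mal and menu:
            u = rng.random(n_mal)
            bounds = np.cumsum([f for _, _, f in menu])
            for ci in range(n_mal):
                j = int(np.searchsorted(bounds, u[ci], side="right"))
                if j < len(menu):
                    prog_assign[ci] = menu[j][0]
        phase_assign = np.empty(n_cells, dtype=object)
        mal_draw = rng.choice(len(phases), size=n_cells, p=phase_probs)
        healthy_draw = rng.choice(len(phases), size=n_cells, p=healthy_phase_probs)
        for ci in range(n_cells):
            phase_assign[ci] = phases[mal_draw[ci] if malignant[ci]
                                      else healthy_draw[ci]]
        size = rng.lognormal(0.0, config.size_factor_sd, size=n_cells)
        pct_mito = rng.beta(*config.pct_mito_law, size=n_cells)

        low_quality = np.zeros(n_cells, dtype=bool)

        # mean model: genes x cells
        mean = np.tile(base[:, None], (1, n_cells))
        for lname, key in (("B", "B_markers"), ("PC", "PC_markers"),
                           ("other", "other_markers")):
            cols = np.flatnonzero(np.array(lineage_per_cell, dtype=object) == lname)
            if len(cols):
                mean[np.ix_(assign[key], cols)] *= config.lineage_marker_fold
        mal_cols = np.flatnonzero(malignant)
        if len(mal_cols):
            mean[np.ix_(assign["core_up"], mal_cols)] *= config.core_up_fold
            mean[np.ix_(assign["core_down"], mal_cols)] *= config.core_down_fold
            for t in config.temporal_genes:
                mean[np.ix_(assign[f"temporal:{t.name}"], mal_cols)] *= \
                    t.profile[stage_pos[stage]]
            for bi, b in enumerate(config.cnv_blocks):
                carrier_cols = mal_cols[np.isin(sub_assign[mal_cols],
                                                list(b.carriers))]
                if len(carrier_cols):
                    mean[np.ix_(block_gene_idx[bi], carrier_cols)] *= b.dosage
            for pname in set(prog_assign[mal_cols]) - {""}:
                key = f"program:{pname}"
                fold = next((f for n_, f, _ in menu if n_ == pname), 3.0)
                cols = np.flatnonzero(prog_assign == pname)
                mean[np.ix_(assign[key], cols)] *= fold
        for pname, key in (("S", "s_genes"), ("G2M", "g2m_genes")):
            cols = np.flatnonzero(phase_assign == pname)
            if len(cols):
                mean[np.ix_(assign[key], cols)] *= config.cc_fold
        mean[tg_idx] = np.where(malignant, base[tg_idx] * config.transgene_fold, 0.0)

        # per-cell depth, then mitochondrial load on top of the nuclear budget
        mean *= size[None, :]
        nonmito_total = mean[nonmito].sum(axis=0) + mean[tg_idx]
        mito_total = pct_mito / (1.0 - pct_mito) * nonmito_total
        mean[mito_idx] = mito_total[None, :] / len(mito_idx)

        counts = rng.negative_binomial(
            config.dispersion,
            config.dispersion / (config.dispersion + np.maximum(mean, 1e-12)),
        ).astype(np.int64)
        counts[mean <= 0] = 0
        counts_blocks.append(sp.csr_matrix(counts))

        for ci in range(n_cells):
            cell_rows.append({
                "cell_id": f"{sample}_c{ci:04d}", "sample": sample, "stage": stage,
                "lineage": lineage_per_cell[ci],
                "malignant": bool(malignant[ci]),
                "subclone": sub_assign[ci], "program": prog_assign[ci],
                "phase": phase_assign[ci], "low_quality": False,
                "size_factor": float(size[ci]),
            })
        true_frac = n_mal / n_cells
        mp = 1.0 / (1.0 + np.exp(-(true_frac - config.mprotein_midpoint)
                                 / config.mprotein_scale))
        mp += rng.normal(0.0, config.mprotein_noise_sd)
        sample_rows.append({"sample": sample, "stage": stage,
                            "malignant_fraction": true_frac, "mprotein": float(mp)})

    # deliberately low-quality cells, appended round-robin across samples
    if config.n_lowquality_cells:
        lq_counts = []
        for i in range(config.n_lowquality_cells):
            sample, stage = samples[i % len(samples)]
            mode = "shallow" if i % 2 == 0 else "mito"
            size_i = 0.02 if mode == "shallow" else 1.0
            pct_i = 0.05 if mode == "shallow" else 0.50
            mean_i = base * size_i
            mean_i[tg_idx] = 0.0
            nm_total = mean_i[nonmito].sum()
            mean_i[mito_idx] = (pct_i / (1 - pct_i)) * nm_total / len(mito_idx)
            c = rng.negative_binomial(
                config.dispersion,
                config.dispersion / (config.dispersion + np.maximum(mean_i, 1e-12)),
            ).astype(np.int64)
            c[mean_i <= 0] = 0
            lq_counts.append(c)
            cell_rows.append({
                "cell_id": f"{sample}_lq{i:03d}", "sample": sample, "stage": stage,
                "lineage": "other", "malignant": False, "subclone": "",
                "program": "", "phase": "G1", "low_quality": True,
                "size_factor": size_i,
            })
        counts_blocks.append(sp.csr_matrix(np.column_stack(lq_counts)))

    counts = sp.hstack(counts_blocks, format="csr")
    cells = pd.DataFrame(cell_rows)
    matrix = ExpressionMatrix(names, cells["cell_id"].to_numpy(), counts)
    cell_table = cells[["cell_id", "sample", "stage"]].copy()
    samples_df = pd.DataFrame(sample_rows)

    gene_sets: dict[str, set[str]] = {
        "core_up": set(names[assign["core_up"]]),
        "core_down": set(names[assign["core_down"]]),
        "plasma_signature": set(names[assign["PC_markers"]][:25]),
        "s_genes": set(names[assign["s_genes"]]),
        "g2m_genes": set(names[assign["g2m_genes"]]),
        "B_markers": set(names[assign["B_markers"]]),
        "PC_markers": set(names[assign["PC_markers"]]),
        "other_markers": set(names[assign["other_markers"]]),
    }
    for key in assign:
        if key.startswith("program:"):
            gene_sets[key] = set(names[assign[key]])

    temporal = pd.DataFrame({
        "gene": [str(names[assign[f"temporal:{t.name}"]][0])
                 for t in config.temporal_genes],
        "label": [t.name for t in config.temporal_genes],
        "fold_early": [t.profile[0] for t in config.temporal_genes],
        "fold_intermediate": [t.profile[1] for t in config.temporal_genes],
        "fold_active": [t.profile[2] for t in config.temporal_genes],
    })

    block_rows = []
    for bi, b in enumerate(config.cnv_blocks):
        for s in b.carriers:
            block_rows.append({"subclone": s, "chromosome": b.chromosome,
                               "dosage": b.dosage,
                               "genes": list(names[block_gene_idx[bi]])})
    cnv_blocks = pd.DataFrame(block_rows)

    # term collection for enrichment analyses: each planted program split
    # into term_size-gene terms, plus random decoys
    enrichment_sets: dict[str, set[str]] = {}
    program_terms: dict[str, set[str]] = {}
    for key in sorted(assign):
        if not key.startswith("program:"):
            continue
        pname = key.split(":", 1)[1]
        members = list(names[assign[key]])
        terms = set()
        for ti in range(0, len(members), config.term_size):
            chunk = members[ti:ti + config.term_size]
            if len(chunk) < 3:
                continue
            tname = f"TERM_{pname}_{ti // config.term_size + 1}"
            enrichment_sets[tname] = set(chunk)
            terms.add(tname)
        program_terms[pname] = terms
    decoy_pool = np.flatnonzero(~np.isin(np.arange(n_genes),
                                         np.concatenate(list(assign.values()))))
    for di in range(config.n_decoy_terms):
        pick = rng.choice(decoy_pool, size=config.term_size, replace=False)
        enrichment_sets[f"TERM_decoy_{di + 1}"] = set(names[pick])

    truth = GroundTruth(cells=cells, samples=samples_df, gene_sets=gene_sets,
                        temporal=temporal, cnv_blocks=cnv_blocks,
                        enrichment_sets=enrichment_sets,
                        program_terms=program_terms)
    logger.info("simulate.simulate_cohort: %d samples, %d cells, %d genes",
                len(samples_df), matrix.n_cells, matrix.n_genes)
    return matrix, cell_table, annotation, truth


def make_reference_profiles(
    truth: GroundTruth,
    matrix: ExpressionMatrix,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Mean log-normalized expression per lineage (genes x lineages).

    Built from healthy cells only (malignant and low-quality cells are
    excluded), standing in for a purified-population bulk reference.
    """
    if matrix.normalized is None:
        lognormalize(matrix)
    cells = truth.cells
    healthy = cells[~cells["malignant"] & ~cells["low_quality"]]
    lineages = sorted(cells["lineage"].unique())
    cols = {}
    for lineage in lineages:
        ids = healthy.loc[healthy["lineage"] == lineage, "cell_id"].to_numpy()
        if len(ids) < min_cells:
            raise ValueError(
                f"lineage {lineage!r} has {len(ids)} healthy cells (< {min_cells})")
        cols[lineage] = matrix.normalized_dense(cells=ids).mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(matrix.gene_ids, name="gene_id"))
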