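# mmprog

Longitudinal single-cell analysis of malignant plasma-cell evolution in a
transgenic (MYC-driven) mouse model of multiple myeloma — from raw UMI
count QC to malignant-cell discrimination, disease-stage expression
programs, expression-inferred CNV subclones, and Jaccard-based subclonal
program similarity. The package is aimed at computational biologists who
want each step of such an analysis as a tested, reusable function rather
than a notebook, together with a synthetic cohort generator that plants
every structure the analysis is designed to recover.

## What it computes

Given gene-by-cell UMI counts with per-cell sample/stage metadata and a
gene annotation (chromosome, start):

* **QC and normalization** — cells with <500 genes, <1,000 UMIs or >15%
  mitochondrial UMIs are removed; genes detected in fewer than 0.1% of the
  average cells per sample are dropped; expression is
  `E = ln(count / total x 10,000 + 1)`.
* **Clustering** — PCA on 3,000 variance-stabilized variable genes (after
  regressing out mitochondrial content), knee-selected components, Leiden
  communities on a shared-nearest-neighbor graph; the resolution is chosen
  from a grid by requiring a minimum number of significant one-vs-rest
  marker genes per cluster and maximizing the median per-cluster mean
  silhouette.
* **Malignant discrimination** — cells are labeled by Spearman correlation
  to reference lineage profiles; B/plasma clusters by >50% majority vote;
  plasma clusters by signature score > 0 and Sdc1 > Cd19; malignant versus
  residual normal plasma cells by cluster-wise transgene expression
  (one-sided rank-sum, Bonferroni).
* **Differential expression** — Wilcoxon rank-sum with detection (>30% or
  >25%) and ln-fold-change (0.5 / 0.25 / 1.0) prefilters, pseudocount
  1/(n cells), Bonferroni over tested genes; exact permutation null for
  groups of ≤25 cells. Term over-representation is hypergeometric with
  BH-FDR.
* **Programs** — the core malignant program (genes DE in the same
  direction versus normal plasma cells at every disease stage);
  stage-specific temporal genes classified as decreasing / peak-early /
  peak-intermediate from per-sample means (t-tests, Bonferroni); and
  similarity programs grouping per-tumour clusters by the Jaccard index of
  their enriched term sets (complete linkage).
* **CNV subclones** — reference-centered log2 expression smoothed along
  each chromosome (101-gene window), denoised against the reference noise
  band, partitioned into subpopulations (Ward on per-chromosome means with
  a silhouette-selected cut), with loss/neutral/gain run-length state
  calls and a subpopulation-by-cluster composition table.
* **Cohort statistics** — Pearson correlation of per-sample malignant
  fraction with the serum M-protein surrogate; pairwise stage comparisons
  (rank-sum, BH).

The synthetic generator (`mmprog.simulate`) emits a 12-sample cohort
(control / early / intermediate / active disease, 800 cells per sample,
2,000 genes) with planted lineages, a transgene expressed only in
malignant cells, whole-chromosome CNV subclones, core/temporal/subclonal
programs, cell-cycle signatures, mitochondrial load, low-quality cells,
and a matching ground-truth table. See `docs/methods.md` for every model
assumption and default.

## Worked example

```python
from mmprog.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig.from_dict({"seed": 3}), "results/run")
r = manifest["results"]
print(r["n_cells_pass_qc"])                 # 9291
print(r["n_malignant"])                     # 1816
print(round(r["malignant_fraction_mprotein_r"], 3))   # 0.968
print(r["mean_within_program_jaccard"])     # {'A': 0.875, 'B': 0.75, 'C': 1.0}
print(r["mean_between_program_jaccard"])    # 0.0
```

Of 9,630 simulated cells, 9,291 pass QC; 1,816 are called malignant
(plasma cells outside the low-transgene cluster), and the per-sample
malignant fraction correlates with the planted M-protein surrogate at
R = 0.968 — the planted monotone disease-burden relation recovered from
called, not true, labels. The similarity analysis groups per-tumour
malignant clusters into shared programs with high within-program Jaccard
index and essentially zero between-program overlap, the
high-within/near-zero-between contrast that distinguishes recurrent from
divergent subclonal transcription. The same run writes the QC report,
cluster labels, annotation, core-program GMT, temporal-gene table, Jaccard
matrix, CNV states and composition tables, plus a `manifest.json` with
SHA-256 digests of every output; rerunning with the same seed reproduces
the digests bit for bit.

The command line mirrors the library:

```bash
mmprog all --out results/run --seed 3          # full pipeline
mmprog qc --out results/qc --seed 3            # any prefix of the stages
mmprog simulate --config run.yaml --out data/  # config file, flags win
```

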