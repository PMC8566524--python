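import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mmprog.io_formats import ExpressionMatrix
from mmprog.preprocess import (filter_genes, lognormalize, qc_filter_cells)
from mmprog.simulate import SimConfig, simulate_cohort


def make_matrix(counts, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    counts = np.asarray(counts)
    g = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    c = cell_ids or [f"c{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(np.array(g, dtype=object), np.array(c, dtype=object),
                            sp.csr_matrix(counts))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by unit tests: 8 samples x 300
    cells, preprocessed through QC, gene filtering and normalization."""
    cfg = SimConfig(seed=11, n_samples_per_stage={s: 2 for s in
                    ("control", "early", "intermediate", "active")},
                    cells_per_sample=450, n_lowquality_cells=10,
                    malignant_fraction_by_stage={"control": 0.0, "early": 0.08,
                                                 "intermediate": 0.15,
                                                 "active": 0.55})
    matrix, cell_table, annotation, truth = simulate_cohort(cfg)
    filtered, report = qc_filter_cells(matrix, annotation)
    sample_of = cell_table.set_index("cell_id")["sample"]
    filtered = filter_genes(filtered, sample_of.reindex(filtered.cell_ids))
    lognormalize(filtered)
    truth_cells = truth.cells.set_index("cell_id").reindex(filtered.cell_ids)
    return {"matrix": filtered, "raw": matrix, "cell_table": cell_table,
            "annotation": annotation, "truth": truth,
            "truth_cells": truth_cells, "qc_report": report, "config": cfg}
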