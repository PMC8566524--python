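"""Core containers and readers/writers for the on-disk formats the pipeline touches.

Count matrices travel as Matrix Market coordinate files with sidecar
``genes.tsv`` / ``barcodes.tsv`` identifier lists (the 10X-style bundle);
gene sets as GMT; everything tabular as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("mmprog")

DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 20)] + ["chrX", "chrM", "chrTg"]
)
#: contigs excluded from positional CNV inference (mitochondrial contig and
#: the transgene placeholder; Y is absent from the default gene model).
NON_CNV_CHROMOSOMES: frozenset[str] = frozenset({"chrM", "chrTg", "chrY"})


@dataclass
class ExpressionMatrix:
    """Gene-by-cell expression container with counts / normalized / scaled layers.

    All layers share the gene and cell orderings of ``gene_ids`` /
    ``cell_ids``; the ``scaled`` layer may cover a gene subset
    (``scaled_genes``), as it is computed on variable genes only.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None
    scaled: np.ndarray | None = None
    scaled_genes: np.ndarray | None = None
    _gene_index: pd.Index = field(init=False, repr=False)
    _cell_index: pd.Index = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self._gene_index = pd.Index(self.gene_ids)
        self._cell_index = pd.Index(self.cell_ids)
        if self._gene_index.has_duplicates:
            dup = self._gene_index[self._gene_index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self._cell_index.has_duplicates:
            dup = self._cell_index[self._cell_index.duplicated()][0]
            raise ValueError(f"duplicate cell identifier: {dup!r}")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"dimension mismatch: counts {self.counts.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative count entry")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_indexer(self, genes) -> np.ndarray:
        idx = self._gene_index.get_indexer(np.asarray(genes, dtype=object))
        if (idx < 0).any():
            missing = list(np.asarray(genes, dtype=object)[idx < 0][:5])
            raise KeyError(f"genes not in matrix: {missing}")
        return idx

    def cell_indexer(self, cells) -> np.ndarray:
        idx = self._cell_index.get_indexer(np.asarray(cells, dtype=object))
        if (idx < 0).any():
            missing = list(np.asarray(cells, dtype=object)[idx < 0][:5])
            raise KeyError(f"cells not in matrix: {missing}")
        return idx

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene/cell identifiers."""
        gi = np.arange(self.n_genes) if genes is None else self.gene_indexer(genes)
        ci = np.arange(self.n_cells) if cells is None else self.cell_indexer(cells)
        out = ExpressionMatrix(
            gene_ids=self.gene_ids[gi],
            cell_ids=self.cell_ids[ci],
            counts=self.counts[gi][:, ci].tocsr(),
        )
        if self.normalized is not None:
            out.normalized = self.normalized[gi][:, ci].tocsr()
        return out

    def normalized_dense(self, genes=None, cells=None) -> np.ndarray:
        """Dense slice of the normalized layer (genes x cells)."""
        if self.normalized is None:
            raise ValueError("normalized layer not computed")
        m = self.normalized
        if genes is not None:
            m = m[self.gene_indexer(genes)]
        if cells is not None:
            m = m[:, self.cell_indexer(cells)]
        return np.asarray(m.todense())


def _read_id_list(path: Path, what: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10X genes.tsv may carry a second (symbol) column; first wins
            ids.append(line.split("\t")[0])
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)
    return ids


def read_counts(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a Matrix Market count bundle into an :class:`ExpressionMatrix`.

    Raises ``ValueError`` on dimension mismatch between the MTX header and
    the identifier files, on duplicate identifiers, and on negative or
    non-integer entries.
    """
    raw = scipy.io.mmread(str(matrix_path))
    genes = _read_id_list(Path(genes_path), "gene")
    cells = _read_id_list(Path(barcodes_path), "barcode")
    if raw.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix header {raw.shape} but "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    coo = sp.coo_matrix(raw)
    if coo.nnz:
        bad = ~np.isclose(coo.data, np.round(coo.data))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"non-integer count at gene {genes[coo.row[i]]!r}, "
                f"cell {cells[coo.col[i]]!r}: {coo.data[i]}"
            )
        if coo.data.min() < 0:
            i = int(np.argmin(coo.data))
            raise ValueError(
                f"negative count at gene {genes[coo.row[i]]!r}, "
                f"cell {cells[coo.col[i]]!r}: {coo.data[i]}"
            )
    counts = sp.csr_matrix(
        (np.round(coo.data).astype(np.int64), (coo.row, coo.col)), shape=raw.shape
    )
    logger.info(
        "io_formats.read_counts: %d genes x %d cells, %d nonzeros",
        len(genes), len(cells), counts.nnz,
    )
    return ExpressionMatrix(np.array(genes, dtype=object),
                            np.array(cells, dtype=object), counts)


def write_counts(matrix: ExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write the counts layer as an MTX bundle (round-trips with read_counts)."""
    scipy.io.mmwrite(str(matrix_path), matrix.counts.tocoo(), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {ln}: expected >= 3 fields, got {len(fields)}")
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"GMT line {ln}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"GMT line {ln}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


def read_gene_annotation(path, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Read the per-gene annotation TSV (gene_id, chromosome, start).

    The mitochondrial flag is inferred from a configurable gene-id prefix
    (case-insensitive, default ``mt-``). Start coordinates are 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    for col in ("gene_id", "chromosome", "start"):
        if col not in df.columns:
            raise ValueError(f"gene annotation missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"gene {dup!r} present twice in annotation")
    if (df["start"] < 0).any():
        bad = df.loc[df["start"] < 0].iloc[0]
        raise ValueError(f"negative start for gene {bad['gene_id']!r}: {bad['start']}")
    df = df[["gene_id", "chromosome", "start"]].copy()
    df["is_mito"] = df["gene_id"].str.lower().str.startswith(mito_prefix.lower())
    return df


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "chromosome", "start"]].to_csv(path, sep="\t", index=False)


def genomic_order(annotation: pd.DataFrame,
                  chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES) -> pd.DataFrame:
    """Return the annotation sorted by (declared chromosome order, start, gene_id).

    The trailing gene_id key makes the order total, hence stable under
    permutation of the input rows. Chromosomes absent from the declared
    order sort after all declared ones, alphabetically.
    """
    rank = {c: i for i, c in enumerate(chromosomes)}
    key = annotation["chromosome"].map(lambda c: rank.get(c, len(rank)))
    out = annotation.assign(_crank=key)
    out = out.sort_values(["_crank", "chromosome", "start", "gene_id"],
                          kind="mergesort").drop(columns="_crank")
    return out.reset_index(drop=True)
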