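"""Core containers and plain-text readers/writers.

The pipeline's universal container is :class:`CellSet` (cells x genes integer
counts plus per-cell metadata) with low-dimensional coordinates carried
separately in :class:`Embedding`.  On disk, counts travel as a Matrix Market
triplet (matrix.mtx + genes/barcodes name files, 10X style), everything else
as headered CSV/TSV.  Internally cells are always rows and indices 0-based;
the 10X convention of genes-as-rows is resolved on read by matching the
declared dimensions against the name-file lengths.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sentinel for cells without an annotation.
UNASSIGNED = "UNASSIGNED"

#: Metadata columns the pipeline knows about.
META_COLUMNS = ("time_h", "sample", "cluster", "label")


@dataclass
class CellSet:
    """Cells x genes count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, cells as rows (dense ndarray or scipy
        sparse; stored as given).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    meta
        Per-cell table indexed like ``cell_ids``; recognised columns are
        ``time_h`` (hours), ``sample``, ``cluster`` and ``label``.
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.counts.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"counts has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"counts has {g} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene ids are not unique")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (np.min(data) < 0 or np.any(data != np.floor(data))):
            raise ValueError("counts must be nonnegative integers")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            if len(self.meta) != n:
                raise ValueError("meta row count does not match cell count")
            self.meta = self.meta.copy()
            self.meta.index = pd.Index(self.cell_ids, name="cell_id")
        if "label" not in self.meta.columns:
            self.meta["label"] = UNASSIGNED

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_cells(self, mask_or_idx) -> "CellSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        counts = self.counts[idx] if not sp.issparse(self.counts) else self.counts.tocsr()[idx]
        return CellSet(
            counts=counts,
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            meta=self.meta.iloc[idx],
        )


@dataclass
class Embedding:
    """Cells x d coordinates in a shared (aligned or PCA) space."""

    coords: np.ndarray
    cell_ids: list[str]
    space_tag: str = "pca"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords rows do not match cell ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def subset_cells(self, mask_or_idx) -> "Embedding":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Embedding(
            coords=self.coords[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            space_tag=self.space_tag,
        )


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        names = [line.strip().split("\t")[0] for line in fh if line.strip()]
    return names


def read_counts_mtx(matrix_path: str, genes_path: str, cells_path: str) -> CellSet:
    """Read a 10X-style Matrix Market triplet into a :class:`CellSet`.

    The on-disk orientation is resolved by matching the matrix dimensions to
    the lengths of the name files; cells always come out as rows.  If both
    orientations are consistent (square matrix with equal name counts) the
    orientation is ambiguous and an error is raised rather than guessed.
    """
    mat = scipy.io.mmread(matrix_path)
    mat = sp.csr_matrix(mat)
    genes = _read_names(genes_path)
    cells = _read_names(cells_path)
    n_rows, n_cols = mat.shape

    genes_rows = n_rows == len(genes) and n_cols == len(cells)
    cells_rows = n_rows == len(cells) and n_cols == len(genes)
    if genes_rows and cells_rows:
        raise ValueError(
            "ambiguous orientation: matrix dimensions match both "
            "genes-as-rows and cells-as-rows; refusing to guess"
        )
    if genes_rows:
        mat = sp.csr_matrix(mat.T)
    elif not cells_rows:
        raise ValueError(
            f"matrix dimensions {mat.shape} match neither {len(genes)} genes "
            f"x {len(cells)} cells nor the transpose"
        )
    if mat.nnz and (mat.data.min() < 0 or np.any(mat.data != np.floor(mat.data))):
        raise ValueError("count matrix has negative or non-integer entries")
    return CellSet(counts=mat, cell_ids=cells, gene_ids=genes)


def write_counts_mtx(cells: CellSet, matrix_path: str, genes_path: str, cells_path: str) -> None:
    """Write a CellSet as a 10X-style triplet (genes x cells on disk)."""
    mat = sp.coo_matrix(cells.counts).T  # genes x cells per 10X convention
    scipy.io.mmwrite(matrix_path, mat, field="integer")
    with open(genes_path, "w") as fh:
        fh.write("\n".join(cells.gene_ids) + "\n")
    with open(cells_path, "w") as fh:
        fh.write("\n".join(cells.cell_ids) + "\n")


def _sep_for(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_metadata(path: str, cellset: CellSet, id_column: str = "cell_id") -> CellSet:
    """Attach per-cell metadata from a delimited table by id join.

    Rows are aligned to the CellSet's cell order, not the file's.  Cells
    missing from the table keep the UNASSIGNED label and NaN time; table rows
    for unknown cells are ignored with a warning.
    """
    table = pd.read_csv(path, sep=_sep_for(path), dtype={id_column: str})
    if id_column not in table.columns:
        raise ValueError(f"metadata table has no '{id_column}' column")
    if table[id_column].duplicated().any():
        dupes = table[id_column][table[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate cell ids in metadata table: {dupes[:5]}")
    table = table.set_index(id_column)
    unknown = table.index.difference(cellset.cell_ids)
    if len(unknown):
        logger.warning(
            "metadata table lists %d cell ids absent from the CellSet; ignored",
            len(unknown),
        )
    aligned = table.reindex(cellset.cell_ids)
    meta = cellset.meta.copy()
    for col in aligned.columns:
        meta[col] = aligned[col].to_numpy()
    if "label" in meta.columns:
        meta["label"] = meta["label"].fillna(UNASSIGNED)
    else:
        meta["label"] = UNASSIGNED
    if "time_h" in meta.columns:
        meta["time_h"] = pd.to_numeric(meta["time_h"], errors="coerce")
    return CellSet(
        counts=cellset.counts,
        cell_ids=list(cellset.cell_ids),
        gene_ids=list(cellset.gene_ids),
        meta=meta,
    )


def write_table(obj: pd.DataFrame, path: str, index: bool = False) -> str:
    """Write a table as delimited text (delimiter from extension)."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    obj.to_csv(path, sep=_sep_for(path), index=index)
    return path


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), **kwargs)


def write_embedding(embedding: Embedding, path: str) -> str:
    """Write an embedding as CSV/TSV with header cell_id, PC1..PCd."""
    cols = [f"PC{i + 1}" for i in range(embedding.dim)]
    df = pd.DataFrame(embedding.coords, columns=cols)
    df.insert(0, "cell_id", embedding.cell_ids)
    return write_table(df, path)


def read_embedding(path: str, space_tag: str = "file") -> Embedding:
    df = read_table(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise ValueError("embedding table has no 'cell_id' column")
    coords = df.drop(columns=["cell_id"]).to_numpy(dtype=float)
    return Embedding(coords=coords, cell_ids=df["cell_id"].tolist(), space_tag=space_tag)
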