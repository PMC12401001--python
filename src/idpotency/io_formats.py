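"""Reading, writing and preprocessing of single-cell count matrices.

Supported formats are Matrix Market coordinate files with 10x-style
``features.tsv``/``barcodes.tsv`` companions (on disk the 10x convention is
genes x cells; matrices are transposed to cells x genes on load) and dense
CSV/TSV tables with an explicit orientation.

Preprocessing follows the standard scRNA-seq quality pipeline: drop cells
below thresholds on total counts, detected genes and mitochondrial fraction;
optionally restrict to a protein-coding gene list; normalize each cell to
relative abundances (rows summing to one).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    ConfigError,
    EmptyFilterError,
    FormatError,
    GeneSelectionError,
    NormalizationError,
)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "CellFilterSpec",
    "FilterReport",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_counts_dense",
    "read_groups_tsv",
    "read_id_list",
    "filter_cells",
    "select_genes",
    "normalize_relative",
]


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer cells x genes matrix with identifiers.

    ``counts`` is stored as CSR; ``group`` is an optional per-cell label
    array (one label per cell).
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, d = self.counts.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != d:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {d} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise FormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != d:
            raise FormatError("duplicate gene identifiers")
        data = self.counts.data
        if data.size and data.min() < 0:
            raise FormatError("negative count entries")
        if not np.allclose(data, np.rint(data)):
            raise FormatError("non-integer count entries")
        self.counts.data = np.rint(data).astype(np.int64)
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if len(self.group) != n:
                raise FormatError("group labels must cover every cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.diff(self.counts.indptr)

    def mito_fraction(self, prefix: str = "MT-") -> np.ndarray:
        """Fraction of each cell's counts carried by mito-prefixed genes."""
        prefix = prefix.lower()
        is_mito = np.array(
            [str(g).lower().startswith(prefix) for g in self.gene_ids]
        )
        totals = self.cell_totals().astype(float)
        if not is_mito.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[:, is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def with_groups(self, groups: pd.Series) -> "CountMatrix":
        """Attach per-cell group labels from a cell_id-indexed Series."""
        missing = [c for c in self.cell_ids if c not in groups.index]
        if missing:
            raise FormatError(
                f"{len(missing)} cells missing from group annotation, "
                f"first: {missing[:5]}"
            )
        labels = groups.loc[list(self.cell_ids)].to_numpy(dtype=object)
        return CountMatrix(self.counts, self.cell_ids, self.gene_ids, labels)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ExpressionMatrix:
    """Cells x genes relative-abundance profiles; every row sums to one."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        row_sums = self.values.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise NormalizationError(
                "expression rows must sum to 1 (use normalize_relative)"
            )
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CellFilterSpec:
    """Thresholds of the three standard cell quality filters."""

    min_total_counts: int = 0
    min_detected_genes: int = 0
    max_mito_fraction: float = 1.0
    mito_gene_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_total_counts < 0 or self.min_detected_genes < 0:
            raise ConfigError("filter thresholds must be nonnegative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_excluded_list: int = 0
    n_low_counts: int = 0
    n_low_genes: int = 0
    n_high_mito: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Load a 10x-style Matrix Market triple as a cells x genes CountMatrix.

    The on-disk matrix is genes x cells (rows match ``features_path``); it is
    transposed on load. Companion files may have 1-3 tab-separated columns;
    the first column supplies the identifier.
    """
    with _open_maybe_gzip(matrix_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.rint(mat.data)):
        bad = mat.data[~np.isclose(mat.data, np.rint(mat.data))][0]
        raise FormatError(f"matrix contains non-integer value {bad}")
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    n_genes, n_cells = mat.shape
    if len(features) != n_genes:
        raise FormatError(
            f"matrix header declares {n_genes} features but features file "
            f"has {len(features)} records"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"matrix header declares {n_cells} barcodes but barcodes file "
            f"has {len(barcodes)} records"
        )
    return CountMatrix(mat.T.tocsr(), barcodes, features)


def write_counts_mtx(cm: CountMatrix, matrix_path, features_path, barcodes_path):
    """Write the 10x-style genes x cells Matrix Market triple."""
    scipy.io.mmwrite(
        str(matrix_path), sp.coo_matrix(cm.counts.T), field="integer"
    )
    with open(features_path, "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\n")
    with open(barcodes_path, "w") as fh:
        for c in cm.cell_ids:
            fh.write(f"{c}\n")


def _read_id_column(path) -> np.ndarray:
    ids = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_counts_dense(path, orientation: str) -> CountMatrix:
    """Read a dense CSV/TSV count table with declared orientation.

    ``orientation`` must be ``cells_by_genes`` or ``genes_by_cells``; the
    file's first column holds row identifiers and the header row column
    identifiers. Orientation is never guessed.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise FormatError(
            f"orientation must be cells_by_genes or genes_by_cells, "
            f"got {orientation!r}"
        )
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("dense count table contains non-numeric entries")
    if np.any(values < 0):
        raise FormatError("dense count table contains negative entries")
    if not np.allclose(values, np.rint(values)):
        raise FormatError("dense count table contains fractional entries")
    if orientation == "genes_by_cells":
        df = df.T
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def read_groups_tsv(path) -> pd.Series:
    """Read a two-column cell_id <tab> group annotation table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group annotation needs two tab-separated columns")
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy())


def read_id_list(path) -> list[str]:
    """Read a plain-text list of identifiers, one per line."""
    with _open_maybe_gzip(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def filter_cells(
    cm: CountMatrix,
    spec: CellFilterSpec,
    exclude_cells: set[str] | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells passing all three quality thresholds.

    A cell survives when total counts >= ``min_total_counts`` AND detected
    genes >= ``min_detected_genes`` AND mito fraction <= ``max_mito_fraction``.
    Cells listed in ``exclude_cells`` (e.g. author-flagged doublets) are
    removed before thresholding. The gene set is never altered.
    """
    keep = np.ones(cm.n_cells, dtype=bool)
    report = FilterReport(n_input=cm.n_cells, n_kept=0)
    if exclude_cells:
        excluded = np.array([c in exclude_cells for c in cm.cell_ids])
        report.n_excluded_list = int(excluded.sum())
        keep &= ~excluded
    totals = cm.cell_totals()
    detected = cm.detected_genes()
    mito = cm.mito_fraction(spec.mito_gene_prefix)
    low_counts = keep & (totals < spec.min_total_counts)
    report.n_low_counts = int(low_counts.sum())
    keep &= ~low_counts
    low_genes = keep & (detected < spec.min_detected_genes)
    report.n_low_genes = int(low_genes.sum())
    keep &= ~low_genes
    high_mito = keep & (mito > spec.max_mito_fraction)
    report.n_high_mito = int(high_mito.sum())
    keep &= ~high_mito
    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        raise EmptyFilterError(
            "all cells removed: matrix empty after filtering "
            f"(thresholds {spec})"
        )
    group = cm.group[keep] if cm.group is not None else None
    out = CountMatrix(
        cm.counts[keep], cm.cell_ids[keep], cm.gene_ids, group
    )
    return out, report


def select_genes(
    cm: CountMatrix,
    gene_list,
    case_fold: bool = False,
) -> CountMatrix:
    """Restrict the matrix to genes in ``gene_list`` (original column order).

    ``gene_list=None`` returns the input unchanged — the escape hatch for
    organisms without a curated protein-coding annotation, where all genes
    in the dataset are used.
    """
    if gene_list is None:
        return cm
    if case_fold:
        wanted = {str(g).casefold() for g in gene_list}
        mask = np.array([str(g).casefold() in wanted for g in cm.gene_ids])
    else:
        wanted = set(gene_list)
        mask = np.array([g in wanted for g in cm.gene_ids])
    if not mask.any():
        unmatched = sorted(str(g) for g in gene_list)[:5]
        raise GeneSelectionError(
            f"no genes in the matrix match the gene list; first unmatched "
            f"ids: {unmatched}"
        )
    group = cm.group if cm.group is not None else None
    return CountMatrix(
        cm.counts[:, mask], cm.cell_ids, cm.gene_ids[mask], group
    )


def normalize_relative(cm: CountMatrix) -> ExpressionMatrix:
    """Divide each cell's counts by its total to get relative abundances."""
    totals = cm.cell_totals().astype(float)
    if np.any(totals <= 0):
        bad = cm.cell_ids[totals <= 0][:5]
        raise NormalizationError(
            f"cells with zero total counts (first: {list(bad)}); "
            "run filter_cells with min_total_counts >= 1 first"
        )
    values = cm.to_dense() / totals[:, None]
    return ExpressionMatrix(values, cm.cell_ids, cm.gene_ids, cm.group)
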