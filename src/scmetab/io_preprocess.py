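"""Input parsing, validation and preprocessing for single-cell expression data.

Conventions used throughout the package:

* expression matrices are genes x cells (genes are rows, cells are columns);
* expression units are one of ``log2tpm1`` (log2(TPM+1)), ``tpm`` or ``counts``;
* all indexing is by gene / cell identifier (pandas), 0-based positional
  indexing internally.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TPM_TOTAL = 1e6
VALID_UNITS = ("log2tpm1", "tpm", "counts")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with a declared unit.

    Parameters
    ----------
    data
        DataFrame with gene ids as the index and cell ids as columns.
        Values must be finite and non-negative.
    unit
        One of ``"log2tpm1"``, ``"tpm"``, ``"counts"``.
    """

    data: pd.DataFrame
    unit: str = "log2tpm1"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dups[:10]}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(cell_ids)], self.unit)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.unit)

    def to_tpm_values(self) -> np.ndarray:
        """Return values on the TPM scale (un-logging if needed)."""
        if self.unit == "log2tpm1":
            return np.exp2(self.values) - 1.0
        if self.unit == "tpm":
            return self.values
        raise ValueError(f"cannot interpret unit {self.unit!r} on the TPM scale")


@dataclass
class CellAnnotation:
    """Per-cell annotation: tumor of origin, cell type and malignant status."""

    table: pd.DataFrame  # index: cell_id; columns: tumor_id, cell_type, malignant

    REQUIRED = ("tumor_id", "cell_type", "malignant")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids in annotation: {dups[:10]}")
        ct = self.table["cell_type"]
        if ct.isna().any() or (ct.astype(str).str.len() == 0).any():
            raise ValueError("annotation contains empty cell_type labels")
        self.table = self.table.assign(malignant=self.table["malignant"].astype(bool))

    @property
    def cell_ids(self) -> pd.Index:
        return self.table.index

    def aligned_to(self, cell_ids) -> "CellAnnotation":
        """Reindex to ``cell_ids``; error naming any cell without annotation."""
        cell_ids = pd.Index(cell_ids)
        missing = cell_ids.difference(self.table.index)
        if len(missing) > 0:
            raise ValueError(
                f"cells present in matrix but not in annotation: {sorted(missing)[:20]}"
            )
        return CellAnnotation(self.table.loc[cell_ids])

    def subset(self, cell_ids) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(cell_ids)])

    def cell_types(self) -> pd.Series:
        return self.table["cell_type"]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), optionally tagged with category labels."""

    sets: dict[str, list[str]]
    categories: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # keep first occurrence, preserving order
                seen: set[str] = set()
                self.sets[name] = [g for g in genes if not (g in seen or seen.add(g))]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {n: len(g) for n, g in self.sets.items()}

    def all_genes(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for genes in self.sets.values():
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def restrict_to(self, gene_ids) -> tuple["GeneSetCollection", dict[str, list[str]]]:
        """Drop genes absent from ``gene_ids``; return the new collection and
        a record of dropped genes per set.  Sets that become empty are removed."""
        universe = set(gene_ids)
        kept: dict[str, list[str]] = {}
        dropped: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            present = [g for g in genes if g in universe]
            gone = [g for g in genes if g not in universe]
            if gone:
                dropped[name] = gone
            if present:
                kept[name] = present
        cats = None
        if self.categories is not None:
            cats = {n: c for n, c in self.categories.items() if n in kept}
        return GeneSetCollection(kept, cats), dropped

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
                name = fields[0]
                if name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
                genes = [g for g in fields[2:] if g]
                sets[name] = genes
        return cls(sets)

    def to_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = (descriptions or {}).get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class GeneLengthTable:
    """gene_id -> transcript length in bases (longest transcript per gene)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.lengths.index.has_duplicates:
            raise ValueError("duplicate gene ids in gene length table")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"non-positive gene lengths for: {bad[:10]}")
        self.lengths = self.lengths.astype(float)

    def for_genes(self, gene_ids) -> pd.Series:
        gene_ids = pd.Index(gene_ids)
        missing = gene_ids.difference(self.lengths.index)
        if len(missing) > 0:
            raise KeyError(f"missing gene lengths for: {sorted(missing)[:20]}")
        return self.lengths.loc[gene_ids]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, unit: str = "log2tpm1") -> ExpressionMatrix:
    """Read a TSV matrix: first column gene id, header row of cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def read_expression_mtx(mtx_path, genes_path=None, barcodes_path=None,
                        unit: str = "counts") -> ExpressionMatrix:
    """Read a MatrixMarket matrix with row (gene) and column (cell) name files."""
    mtx_path = Path(mtx_path)
    genes_path = Path(genes_path) if genes_path else mtx_path.with_name("genes.tsv")
    barcodes_path = Path(barcodes_path) if barcodes_path else mtx_path.with_name("barcodes.tsv")
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    return ExpressionMatrix(df, unit)


def read_annotation(path) -> CellAnnotation:
    """Read a cell annotation TSV with columns cell_id, tumor_id, cell_type, malignant."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError("annotation file must have a 'cell_id' column")
    df = df.set_index("cell_id")
    mal = df["malignant"].str.lower().map(
        {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    )
    if mal.isna().any():
        raise ValueError("malignant column must be boolean-like (true/false/1/0/yes/no)")
    df["malignant"] = mal
    return CellAnnotation(df)


def read_gene_lengths(path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneLengthTable(df.iloc[:, 0])


def read_inputs(matrix_path, annotation_path, gmt_path, lengths_path=None,
                unit: str = "log2tpm1"):
    """Read and cross-validate all pipeline inputs.

    Returns ``(matrix, annotation, gene_sets, lengths_or_None)``.  The
    annotation is aligned to the matrix columns (a matrix cell absent from the
    annotation is a hard error naming the offenders); gene-set genes absent
    from the matrix are dropped with a warning.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        matrix = read_expression_mtx(matrix_path, unit=unit)
    else:
        matrix = read_expression_tsv(matrix_path, unit=unit)
    annotation = read_annotation(annotation_path).aligned_to(matrix.cell_ids)
    gene_sets = GeneSetCollection.from_gmt(gmt_path)
    gene_sets, dropped = gene_sets.restrict_to(matrix.gene_ids)
    if dropped:
        n = sum(len(v) for v in dropped.values())
        warnings.warn(
            f"{n} gene-set genes absent from the matrix were dropped "
            f"(first sets affected: {list(dropped)[:5]})"
        )
    lengths = read_gene_lengths(lengths_path) if lengths_path else None
    return matrix, annotation, gene_sets, lengths


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def filter_small_groups(matrix: ExpressionMatrix, annotation: CellAnnotation,
                        min_cells: int = 50) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Remove under-populated groups: malignant cells are grouped by tumor,
    non-malignant cells by cell type; any group with fewer than ``min_cells``
    cells is dropped.  A tumor's non-malignant cells are kept even when its
    malignant group is removed."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    ann = annotation.aligned_to(matrix.cell_ids).table
    mal = ann["malignant"]
    tumor_sizes = ann.loc[mal, "tumor_id"].value_counts()
    type_sizes = ann.loc[~mal, "cell_type"].value_counts()
    ok_tumors = set(tumor_sizes.index[tumor_sizes >= min_cells])
    ok_types = set(type_sizes.index[type_sizes >= min_cells])
    keep = (mal & ann["tumor_id"].isin(ok_tumors)) | (~mal & ann["cell_type"].isin(ok_types))
    kept_cells = ann.index[keep]
    if len(kept_cells) == 0:
        raise ValueError(f"all cells removed by the min_cells={min_cells} group filter")
    return matrix.subset_cells(kept_cells), CellAnnotation(ann.loc[kept_cells])


def dropout_rates(matrix: ExpressionMatrix, annotation: CellAnnotation | None = None,
                  by_group: str | None = None):
    """Per-gene fraction of cells with zero expression.

    With ``by_group`` (an annotation column, e.g. ``"cell_type"``) returns a
    genes x groups DataFrame; otherwise a per-gene Series.
    """
    if matrix.n_cells == 0:
        raise ValueError("matrix has no cells")
    zero = matrix.data == 0
    if by_group is None:
        return zero.mean(axis=1)
    if annotation is None:
        raise ValueError("by_group requires an annotation")
    groups = annotation.aligned_to(matrix.cell_ids).table[by_group]
    return zero.T.groupby(groups).mean().T


def _neighbor_mean_impute(values: np.ndarray, target_rows: np.ndarray,
                          highconf_rows: np.ndarray, cols: np.ndarray,
                          n_neighbors: int) -> None:
    """In-place neighbor-mean imputation of zeros in ``target_rows`` for the
    cell columns ``cols``, using correlation distance over high-confidence genes."""
    if len(cols) < 2:
        return
    ref = values[np.ix_(highconf_rows, cols)] if highconf_rows.size else values[:, cols]
    # correlation distance between cells; constant/degenerate profiles get
    # zero similarity
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ref.T)
    corr = np.atleast_2d(corr)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, np.inf)
    k = min(n_neighbors, len(cols) - 1)
    order = np.argsort(dist, axis=1)[:, :k]  # per-cell neighbor indices (local)
    sub = values[np.ix_(target_rows, cols)]
    for j in range(len(cols)):
        nb_mean = sub[:, order[j]].mean(axis=1)
        zero = sub[:, j] == 0
        values[target_rows[zero], cols[j]] = nb_mean[zero]


def impute_dropouts(matrix: ExpressionMatrix, dropout_threshold: float = 0.5,
                    method: str = "neighbor_mean",
                    annotation: CellAnnotation | None = None,
                    n_neighbors: int = 10) -> ExpressionMatrix:
    """Impute dropout zeros, restricted to genes whose dropout rate exceeds
    ``dropout_threshold`` (over-imputation guard).

    Contract honoured by any method: genes at/below the threshold are
    bit-identical to the input; nonzero entries are never modified; imputed
    values are non-negative.  The default ``neighbor_mean`` method replaces a
    zero by the mean of the gene over the cell's ``n_neighbors`` nearest
    neighbor cells (correlation distance over the high-confidence genes,
    within the same cell type when an annotation is given); a zero whose
    neighbors are all zero stays zero.
    """
    if not (0.0 <= dropout_threshold <= 1.0):
        raise ValueError("dropout_threshold must be in [0, 1]")
    if matrix.unit not in ("log2tpm1", "tpm"):
        raise ValueError("imputation expects log2tpm1 or tpm values")
    if method != "neighbor_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    rates = dropout_rates(matrix).to_numpy()
    target_rows = np.flatnonzero(rates > dropout_threshold)
    if target_rows.size == 0:
        return ExpressionMatrix(matrix.data.copy(), matrix.unit)
    highconf_rows = np.flatnonzero(rates <= dropout_threshold)
    values = matrix.values  # fresh copy
    if annotation is not None:
        types = annotation.aligned_to(matrix.cell_ids).table["cell_type"].to_numpy()
        for ct in pd.unique(types):
            cols = np.flatnonzero(types == ct)
            _neighbor_mean_impute(values, target_rows, highconf_rows, cols, n_neighbors)
    else:
        _neighbor_mean_impute(values, target_rows, highconf_rows,
                              np.arange(matrix.n_cells), n_neighbors)
    out = pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.cell_ids)
    return ExpressionMatrix(out, matrix.unit)


def pool_to_bulk(matrix: ExpressionMatrix, annotation: CellAnnotation,
                 group_by: str = "tumor_id", groups=None) -> ExpressionMatrix:
    """Reconstruct pseudo-bulk profiles: per group, average the TPM values of
    its cells and return in the input unit (re-logged for log2tpm1 input).

    ``groups`` optionally restricts/orders the groups pooled (e.g. to pool a
    single cell-type negative control).
    """
    ann = annotation.aligned_to(matrix.cell_ids).table
    labels = ann[group_by]
    wanted = list(pd.unique(labels)) if groups is None else list(groups)
    tpm = matrix.to_tpm_values()
    cols = {}
    for g in wanted:
        idx = np.flatnonzero((labels == g).to_numpy())
        if idx.size == 0:
            raise ValueError(f"group {g!r} has no cells to pool")
        cols[str(g)] = tpm[:, idx].mean(axis=1)
    pooled = pd.DataFrame(cols, index=matrix.gene_ids)
    if matrix.unit == "log2tpm1":
        pooled = np.log2(pooled + 1.0)
    return ExpressionMatrix(pooled, matrix.unit)
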