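"""Size-factor normalization for single-cell count data.

Implements four size-factor estimators — relative log expression (RLE),
trimmed mean of M-values (TMM), upper quartile and cell-type–aware
pooling/deconvolution — together with the TPM<->pseudo-count conversion and a
data-driven criterion for choosing among the methods: the method minimizing
the differences in distributions of relative gene expression levels between
cell types wins.

All estimators use only "reference genes", genes with dropout rate below a
threshold (default 0.75, i.e. detected in at least 25% of cells), to avoid
noise from low-expressed and undetected genes.  Counts reconstructed from TPM
are pseudo-counts; nothing here assumes integer counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_preprocess import (
    TPM_TOTAL,
    CellAnnotation,
    ExpressionMatrix,
    GeneLengthTable,
    GeneSetCollection,
)

METHODS = ("rle", "tmm", "upper_quartile", "deconvolution")

#: pool sizes for deconvolution (capped at the cell-type group size)
DECONV_POOL_SIZES = (20, 40, 60, 80, 100)
#: weight of the library-size anchor equations in the deconvolution system
DECONV_ANCHOR_WEIGHT = 0.01


@dataclass
class SizeFactors:
    """Per-cell scaling factors.  RLE factors have geometric mean 1; the
    other methods are rescaled to arithmetic mean 1."""

    factors: pd.Series  # cell_id -> factor
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError("size factors must be positive and finite")

    def for_cells(self, cell_ids) -> pd.Series:
        cell_ids = pd.Index(cell_ids)
        missing = cell_ids.difference(self.factors.index)
        if len(missing) > 0:
            raise KeyError(f"size factors missing for cells: {sorted(missing)[:10]}")
        return self.factors.loc[cell_ids]


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def tpm_counts_convert(matrix: ExpressionMatrix, lengths: GeneLengthTable,
                       direction: str) -> ExpressionMatrix:
    """Convert TPM values to pseudo-counts (value x gene length) or back.

    The round trip is the identity up to floating error; ``to_tpm`` divides
    by length and therefore assumes the counts were produced this way (no
    per-cell re-normalization is applied).
    """
    L = lengths.for_genes(matrix.gene_ids).to_numpy()
    if direction == "to_counts":
        if matrix.unit != "tpm":
            raise ValueError(f"to_counts expects unit 'tpm', got {matrix.unit!r}")
        out = matrix.data.mul(L, axis=0)
        return ExpressionMatrix(out, "counts")
    if direction == "to_tpm":
        if matrix.unit != "counts":
            raise ValueError(f"to_tpm expects unit 'counts', got {matrix.unit!r}")
        out = matrix.data.div(L, axis=0)
        return ExpressionMatrix(out, "tpm")
    raise ValueError(f"direction must be 'to_counts' or 'to_tpm', got {direction!r}")


# ---------------------------------------------------------------------------
# size-factor estimators (each works on a reference-gene count submatrix)
# ---------------------------------------------------------------------------

def _reference_gene_mask(counts: np.ndarray, max_dropout: float) -> np.ndarray:
    return (counts == 0).mean(axis=1) < max_dropout


def _rle_factors(counts: np.ndarray) -> np.ndarray:
    # classic median-of-ratios: geometric mean over cells, per gene, using
    # genes positive in every cell
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("RLE: no reference gene is positive in every cell")
    ref = counts[allpos]
    gm = np.exp(np.log(ref).mean(axis=1))
    return np.median(ref / gm[:, None], axis=0)


def _upper_quartile_factors(counts: np.ndarray) -> np.ndarray:
    n = counts.shape[1]
    uq = np.empty(n)
    for j in range(n):
        nz = counts[counts[:, j] > 0, j]
        if nz.size == 0:
            raise ValueError(f"cell column {j} has zero counts on all reference genes")
        uq[j] = np.percentile(nz, 75)
    return uq


def _tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
                 ) -> np.ndarray:
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("cell with zero counts on all reference genes")
    # reference cell: upper quartile of count/library closest to the mean UQ
    with np.errstate(divide="ignore"):
        f75 = np.array([np.percentile(counts[:, j] / lib[j], 75)
                        for j in range(counts.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = counts[:, ref_j], lib[ref_j]
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        yc, nc = counts[:, j], lib[j]
        ok = (yc > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"cell column {j} shares no expressed reference gene with "
                             "the TMM reference cell")
        m = np.log2((yc[ok] / nc) / (yr[ok] / nr))
        a = 0.5 * np.log2((yc[ok] / nc) * (yr[ok] / nr))
        w = (nc - yc[ok]) / (nc * yc[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        tmm = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        # size factor scales counts directly: normalization factor x library size
        factors[j] = (2.0 ** tmm) * nc
    return factors


def _ring_order(lib: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
    """Arrange cells on a ring with smoothly varying library size: ascending
    odd ranks up one side, even ranks down the other.  Library-size ties are
    broken by cell id so the ring is invariant to input order."""
    asc = np.lexsort((tiebreak, lib))
    return np.concatenate([asc[::2], asc[1::2][::-1]])


def _deconvolution_group(counts: np.ndarray, pool_sizes,
                         tiebreak: np.ndarray) -> np.ndarray:
    """Pooling/deconvolution factors for one cell-type group (relative scale).

    Pools of consecutive cells on a library-size ring are summed; each pool
    sum is compared to the group's average profile by a median ratio, giving
    one linear equation (pool factor = sum of member cell factors).  Low-weight
    anchor equations tying each cell to its library-size factor make the
    system full rank (ring systems alone are rank-deficient for many group
    sizes).
    """
    n = counts.shape[1]
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("cell with zero counts on all reference genes")
    ring = _ring_order(lib, tiebreak)
    ref_profile = counts.mean(axis=1)
    ok = ref_profile > 0
    sizes = sorted({min(int(s), n) for s in pool_sizes})
    rows, rhs = [], []
    for s in sizes:
        if s < 1:
            continue
        for start in range(n):
            members = ring[np.arange(start, start + s) % n]
            pooled = counts[:, members].sum(axis=1)
            theta = np.median(pooled[ok] / ref_profile[ok])
            row = np.zeros(n)
            row[members] = 1.0
            rows.append(row)
            rhs.append(theta)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    # anchor to library-size factors at low weight
    anchor = DECONV_ANCHOR_WEIGHT * np.eye(n)
    lib_factor = lib / lib.mean()
    A = np.vstack([A, anchor])
    b = np.concatenate([b, DECONV_ANCHOR_WEIGHT * lib_factor])
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n:
        raise ValueError(
            "deconvolution linear system is rank-deficient; use larger pool sizes "
            "or larger cell-type groups"
        )
    if (sol <= 0).any():
        raise ValueError(
            "deconvolution produced non-positive factors; use larger pool sizes"
        )
    return sol


def size_factors(counts: ExpressionMatrix, method: str,
                 annotation: CellAnnotation | None = None,
                 reference_dropout_max: float = 0.75,
                 pool_sizes=DECONV_POOL_SIZES) -> SizeFactors:
    """Estimate per-cell size factors from a (pseudo-)count matrix.

    ``method`` is one of ``rle``, ``tmm``, ``upper_quartile``,
    ``deconvolution``.  Only reference genes (dropout rate <
    ``reference_dropout_max``) enter the computation.  Deconvolution requires
    a cell annotation: factors are estimated within each cell type and the
    groups are then rescaled to a common reference via their mean profiles.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if counts.unit != "counts":
        raise ValueError("size factors are estimated on counts")
    if counts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    vals = counts.values
    mask = _reference_gene_mask(vals, reference_dropout_max)
    if not mask.any():
        raise ValueError("no reference genes pass the dropout filter")
    ref = vals[mask]
    if (ref.sum(axis=0) == 0).any():
        bad = counts.cell_ids[ref.sum(axis=0) == 0].tolist()
        raise ValueError(f"cells with zero counts on all reference genes: {bad[:10]}")

    if method == "rle":
        f = _rle_factors(ref)
        f = f / scipy.stats.gmean(f)
    elif method == "upper_quartile":
        f = _upper_quartile_factors(ref)
        f = f / f.mean()
    elif method == "tmm":
        f = _tmm_factors(ref)
        f = f / f.mean()
    else:  # deconvolution
        if annotation is None:
            raise ValueError("deconvolution requires a cell annotation")
        ann = annotation.aligned_to(counts.cell_ids).table
        types = ann["cell_type"].to_numpy()
        f = np.empty(counts.n_cells)
        group_scale: dict[str, float] = {}
        overall = ref.mean(axis=1)
        ok = overall > 0
        for ct in pd.unique(types):
            cols = np.flatnonzero(types == ct)
            sub = ref[:, cols]
            ids = counts.cell_ids.to_numpy(dtype=object)[cols]
            g = _deconvolution_group(sub, pool_sizes, ids)
            g = g / g.mean()
            # cross-group rescaling: group mean profile vs overall mean profile
            scale = np.median(sub.mean(axis=1)[ok] / overall[ok])
            f[cols] = g * scale
            group_scale[str(ct)] = float(scale)
        f = f / f.mean()
    return SizeFactors(pd.Series(f, index=counts.cell_ids), method)


def apply_size_factors(counts: ExpressionMatrix, factors: SizeFactors,
                       lengths: GeneLengthTable) -> ExpressionMatrix:
    """Divide counts by per-cell factors, transform back to TPM by dividing by
    gene lengths and rescaling each cell to the TPM total, and return
    log2(TPM+1) values."""
    f = factors.for_cells(counts.cell_ids).to_numpy()
    L = lengths.for_genes(counts.gene_ids).to_numpy()
    norm = counts.values / f[None, :]
    rate = norm / L[:, None]
    total = rate.sum(axis=0)
    if (total == 0).any():
        raise ValueError("cell with all-zero normalized counts")
    tpm = rate / total[None, :] * TPM_TOTAL
    out = pd.DataFrame(np.log2(tpm + 1.0), index=counts.gene_ids, columns=counts.cell_ids)
    return ExpressionMatrix(out, "log2tpm1")


# ---------------------------------------------------------------------------
# method selection
# ---------------------------------------------------------------------------

def evaluate_normalizations(counts: ExpressionMatrix, annotation: CellAnnotation,
                            lengths: GeneLengthTable,
                            gene_sets: GeneSetCollection | None = None,
                            methods=METHODS,
                            reference_dropout_max: float = 0.75) -> pd.DataFrame:
    """Rank size-factor methods by how similar the distributions of relative
    gene expression are between cell types after normalization.

    For each method the counts are normalized, cell-type mean expression and
    relative expression r_{i,j} are computed (optionally restricted to the
    genes of ``gene_sets``), and the score is the mean two-sample
    Kolmogorov–Smirnov statistic of log r between all cell-type pairs.
    Returns a DataFrame sorted ascending by score (best method first).
    """
    from .pathway_activity import celltype_means, relative_expression

    ann = annotation.aligned_to(counts.cell_ids)
    if ann.table["cell_type"].nunique() < 2:
        raise ValueError("need at least two cell types to evaluate normalizations")
    rows = []
    for method in methods:
        sf = size_factors(counts, method, annotation=ann,
                          reference_dropout_max=reference_dropout_max)
        normed = apply_size_factors(counts, sf, lengths)
        if gene_sets is not None:
            keep = [g for g in gene_sets.all_genes() if g in normed.gene_ids]
            normed = normed.subset_genes(keep)
        means = celltype_means(normed, ann)
        rel = relative_expression(means)
        r = rel.r.loc[rel.valid_mask]
        types = list(r.columns)
        stats = []
        for a in range(len(types)):
            for b in range(a + 1, len(types)):
                ra = r[types[a]].to_numpy()
                rb = r[types[b]].to_numpy()
                la, lb = np.log(ra[ra > 0]), np.log(rb[rb > 0])
                stats.append(scipy.stats.ks_2samp(la, lb).statistic
                             if la.size and lb.size else np.nan)
        rows.append({"method": method, "score": float(np.nanmean(stats))})
    out = pd.DataFrame(rows).sort_values(["score", "method"], kind="stable")
    return out.reset_index(drop=True)
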