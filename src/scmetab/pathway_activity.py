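"""Cell-type pathway activity scoring with permutation significance.

The score for pathway t in cell type (or sample group) j is a weighted average
of relative expression over the pathway's member genes:

* E_{i,j}: mean expression of gene i across the cells of type j;
* r_{i,j} = E_{i,j} / mean_j(E_{i,j}): relative expression (1 = average);
* p_{t,j} = sum_i w_i r_{i,j} / sum_i w_i over member genes, where
  w_i = 1 / (number of pathways containing gene i).

Genes whose relative expression is extreme within a pathway (any r above
3x the 75th percentile or below 1/3x the 25th percentile of the pathway's
pooled r values) are excluded from that pathway before scoring, guarding
against low-expression / high-dropout artifacts.

Significance comes from a label-permutation test: cell-type labels are
shuffled, the whole E -> r -> p chain (outlier rule included) is recomputed
per shuffle, and the observed score is compared to the null scores in the
direction of its deviation from 1.  The default p-value doubles that
one-sided tail (capped at 1) so that p is uniform under the null; the raw
one-sided fraction is available via ``tail="observed"``, and the add-one
smoothing can be disabled to recover a plain fraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import CellAnnotation, ExpressionMatrix, GeneSetCollection


@dataclass
class CellTypeMeans:
    """Gene x cell-type (or group) mean expression, with group sizes."""

    E: pd.DataFrame
    group_sizes: pd.Series

    @property
    def groups(self) -> pd.Index:
        return self.E.columns


@dataclass
class RelativeExpression:
    """Gene x group relative expression; genes with across-group mean 0 are
    invalid and excluded downstream."""

    r: pd.DataFrame
    valid_mask: pd.Series


@dataclass
class PathwayActivityTable:
    """Pathway x group activity scores with optional permutation p-values.

    Scores are NaN (flagged in ``undefined``) for pathways with no surviving
    member gene; p-values live in (0, 1].
    """

    scores: pd.DataFrame
    p_values: pd.DataFrame | None = None
    excluded_outlier_genes: dict[str, list[str]] = field(default_factory=dict)
    n_genes_used: pd.Series | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def undefined(self) -> list[str]:
        return self.scores.index[self.scores.isna().all(axis=1)].tolist()

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: pathway, group, score[, p_value]."""
        long = self.scores.stack(future_stack=True).rename("score").reset_index()
        long.columns = ["pathway", "group", "score"]
        if self.p_values is not None:
            pv = self.p_values.stack(future_stack=True).rename("p_value").reset_index()
            pv.columns = ["pathway", "group", "p_value"]
            long = long.merge(pv, on=["pathway", "group"])
        if self.n_genes_used is not None:
            long["n_genes_used"] = long["pathway"].map(self.n_genes_used)
        return long


# ---------------------------------------------------------------------------
# Eq. 1-3 building blocks
# ---------------------------------------------------------------------------

def celltype_means(matrix: ExpressionMatrix, annotation: CellAnnotation,
                   group_col: str = "cell_type") -> CellTypeMeans:
    """Arithmetic mean expression per gene per cell type (E_{i,j})."""
    ann = annotation.aligned_to(matrix.cell_ids).table
    labels = ann[group_col]
    sizes = labels.value_counts()
    empty = sizes.index[sizes == 0]
    if len(empty):
        warnings.warn(f"groups with zero cells excluded: {list(empty)}")
    E = matrix.data.T.groupby(labels, observed=True).mean().T
    return CellTypeMeans(E, sizes.loc[E.columns])


def relative_expression(means: CellTypeMeans) -> RelativeExpression:
    """Relative expression r_{i,j}: E_{i,j} divided by the across-group mean.

    For every valid gene the across-group mean of r is exactly 1.  Genes with
    across-group mean 0 are flagged invalid.
    """
    if means.E.shape[1] < 2:
        raise ValueError("relative expression needs at least two groups")
    row_mean = means.E.mean(axis=1)
    valid = row_mean > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = means.E.div(row_mean, axis=0)
    r[~valid] = np.nan
    return RelativeExpression(r, valid)


def gene_weights(gene_sets: GeneSetCollection) -> pd.Series:
    """w_i = 1 / number of gene sets that contain gene i (over set members)."""
    counts: dict[str, int] = {}
    for _, genes in gene_sets:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series({g: 1.0 / c for g, c in counts.items()}, name="weight")


def _pathway_score_block(r_block: np.ndarray, w: np.ndarray,
                         outlier_hi: float, outlier_lo: float):
    """Score one pathway from its member-gene r values (m x N, NaN rows invalid).

    Returns (scores per group, surviving-gene boolean mask)."""
    valid = ~np.isnan(r_block).any(axis=1)
    pool = r_block[valid]
    if pool.size == 0:
        return None, valid
    q25, q75 = np.percentile(pool, [25, 75])
    out = (pool > outlier_hi * q75).any(axis=1) | (pool < outlier_lo * q25).any(axis=1)
    survive = valid.copy()
    survive[valid] = ~out
    if not survive.any():
        return None, survive
    ws = w[survive]
    scores = ws @ r_block[survive] / ws.sum()
    return scores, survive


def pathway_scores(relexpr: RelativeExpression, gene_sets: GeneSetCollection,
                   weights: pd.Series | None = None,
                   outlier_hi: float = 3.0, outlier_lo: float = 1.0 / 3.0
                   ) -> PathwayActivityTable:
    """Weighted-average pathway activity scores with per-pathway outlier
    exclusion.  ``weights`` defaults to reciprocal pathway membership computed
    from the SAME gene-set collection."""
    if weights is None:
        weights = gene_weights(gene_sets)
    r = relexpr.r
    groups = r.columns
    rows, n_used, outliers = {}, {}, {}
    for name, genes in gene_sets:
        present = [g for g in genes if g in r.index]
        if not present:
            rows[name] = np.full(len(groups), np.nan)
            n_used[name] = 0
            continue
        block = r.loc[present].to_numpy()
        w = weights.loc[present].to_numpy()
        scores, survive = _pathway_score_block(block, w, outlier_hi, outlier_lo)
        valid = ~np.isnan(block).any(axis=1)
        removed = [g for g, v, s in zip(present, valid, survive) if v and not s]
        if removed:
            outliers[name] = removed
        if scores is None:
            warnings.warn(f"pathway {name!r} has no surviving genes; score undefined")
            rows[name] = np.full(len(groups), np.nan)
            n_used[name] = 0
        else:
            rows[name] = scores
            n_used[name] = int(survive.sum())
    table = pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    table.index.name = "pathway"
    return PathwayActivityTable(table, excluded_outlier_genes=outliers,
                                n_genes_used=pd.Series(n_used))


# ---------------------------------------------------------------------------
# permutation test (fast numpy path reused per shuffle)
# ---------------------------------------------------------------------------

def _group_mean_r(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Relative expression matrix from raw values and integer group codes."""
    onehot = np.zeros((codes.size, n_groups))
    onehot[np.arange(codes.size), codes] = 1.0
    counts = onehot.sum(axis=0)
    E = (values @ onehot) / counts[None, :]
    row_mean = E.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = E / row_mean[:, None]
    r[row_mean <= 0] = np.nan
    return r


def _all_pathway_scores(r: np.ndarray, set_rows: list[np.ndarray],
                        set_weights: list[np.ndarray],
                        outlier_hi: float, outlier_lo: float) -> np.ndarray:
    n_groups = r.shape[1]
    out = np.full((len(set_rows), n_groups), np.nan)
    for t, (rows, w) in enumerate(zip(set_rows, set_weights)):
        scores, _ = _pathway_score_block(r[rows], w, outlier_hi, outlier_lo)
        if scores is not None:
            out[t] = scores
    return out


def _permutation_p(matrix_values: np.ndarray, codes: np.ndarray, n_groups: int,
                   set_rows, set_weights, outlier_hi, outlier_lo,
                   n_perm: int, rng: np.random.Generator,
                   tail: str, smoothing: bool):
    r_obs = _group_mean_r(matrix_values, codes, n_groups)
    obs = _all_pathway_scores(r_obs, set_rows, set_weights, outlier_hi, outlier_lo)
    larger = np.zeros_like(obs)
    smaller = np.zeros_like(obs)
    valid_null = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        r_null = _group_mean_r(matrix_values, perm, n_groups)
        null = _all_pathway_scores(r_null, set_rows, set_weights, outlier_hi, outlier_lo)
        ok = ~np.isnan(null)
        larger += np.where(ok & (null > obs), 1.0, 0.0)
        smaller += np.where(ok & (null < obs), 1.0, 0.0)
        valid_null += np.where(ok, 1.0, 0.0)
    count = np.where(obs > 1.0, larger, smaller)
    if smoothing:
        p_one = (1.0 + count) / (1.0 + valid_null)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p_one = count / valid_null
    if tail == "two-sided":
        p = np.minimum(1.0, 2.0 * p_one)
    elif tail == "observed":
        p = p_one
    else:
        raise ValueError(f"tail must be 'two-sided' or 'observed', got {tail!r}")
    p = np.where(obs == 1.0, 1.0, p)
    p = np.where(np.isnan(obs), np.nan, p)
    return obs, p


def _prepare_sets(gene_ids: pd.Index, gene_sets: GeneSetCollection,
                  weights: pd.Series):
    index = {g: i for i, g in enumerate(gene_ids)}
    names, set_rows, set_weights = [], [], []
    for name, genes in gene_sets:
        rows = np.array([index[g] for g in genes if g in index], dtype=int)
        names.append(name)
        set_rows.append(rows)
        set_weights.append(weights.reindex([gene_ids[i] for i in rows]).to_numpy()
                           if rows.size else np.empty(0))
    return names, set_rows, set_weights


def permutation_test(matrix: ExpressionMatrix, annotation: CellAnnotation,
                     gene_sets: GeneSetCollection, n_perm: int = 5000,
                     seed: int | None = None, group_col: str = "cell_type",
                     outlier_hi: float = 3.0, outlier_lo: float = 1.0 / 3.0,
                     tail: str = "two-sided", smoothing: bool = True
                     ) -> PathwayActivityTable:
    """Pathway activity scores with label-shuffling permutation p-values.

    Cell-type labels are globally shuffled ``n_perm`` times and the full
    mean -> relative-expression -> weighted-score chain is recomputed for each
    shuffle.  For an observed score above 1 the one-sided tail counts null
    scores that are larger; below 1, smaller.  ``tail="two-sided"`` (default)
    doubles that tail so the p-value is calibrated; ``tail="observed"``
    returns the raw directional fraction.  With ``smoothing`` the add-one
    estimator (1+x)/(1+n) keeps p strictly positive.  Scores exactly 1 get
    p = 1.  Reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ann = annotation.aligned_to(matrix.cell_ids).table
    labels = ann[group_col].to_numpy()
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("permutation test needs at least two groups")
    weights = gene_weights(gene_sets)
    names, set_rows, set_weights = _prepare_sets(matrix.gene_ids, gene_sets, weights)
    rng = np.random.default_rng(seed)
    obs, p = _permutation_p(matrix.values, codes, len(groups), set_rows, set_weights,
                            outlier_hi, outlier_lo, n_perm, rng, tail, smoothing)
    scores = pd.DataFrame(obs, index=pd.Index(names, name="pathway"), columns=groups)
    pvals = pd.DataFrame(p, index=scores.index, columns=groups)
    # outlier bookkeeping on the observed labeling
    observed = pathway_scores(
        relative_expression(celltype_means(matrix, CellAnnotation(ann), group_col)),
        gene_sets, weights, outlier_hi, outlier_lo)
    return PathwayActivityTable(scores, pvals, observed.excluded_outlier_genes,
                                observed.n_genes_used, n_perm=n_perm, seed=seed)


def bulk_group_activity(bulk_matrix: ExpressionMatrix, sample_labels: pd.Series,
                        gene_sets: GeneSetCollection, n_perm: int = 1000,
                        seed: int | None = None, **kwargs) -> PathwayActivityTable:
    """Pathway activity for bulk samples grouped e.g. tumor vs normal: the
    identical machinery with sample groups in the role of cell types
    (default 1000 permutations)."""
    sample_labels = pd.Series(sample_labels)
    ann = CellAnnotation(pd.DataFrame({
        "tumor_id": "bulk", "cell_type": sample_labels.astype(str),
        "malignant": False}, index=sample_labels.index))
    return permutation_test(bulk_matrix, ann, gene_sets, n_perm=n_perm,
                            seed=seed, **kwargs)
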