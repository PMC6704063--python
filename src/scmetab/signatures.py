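"""Per-cell gene-set scores, correlation analyses and cluster agreement.

A cell's score for a gene program (glycolysis, OXPHOS, the hypoxia-response
signature, ...) is the unweighted mean log2(TPM+1) expression of the set's
genes present in the matrix.  Score-score and gene-gene correlations use
standard Pearson/Spearman statistics; agreement between two clusterings is
summarized by relative mutual information, I(A;B) / min(H(A), H(B)) with
natural-log entropies — 1 when either partition determines the other, ~0 for
independent labelings.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import mutual_info_score

from .io_preprocess import ExpressionMatrix, GeneSetCollection


@dataclass
class CellSetScore:
    """cell_id -> mean expression of a named gene set."""

    scores: pd.Series
    set_name: str
    n_genes_used: int


def cell_set_score(matrix: ExpressionMatrix, gene_set, set_name: str = ""
                   ) -> CellSetScore:
    """Unweighted per-cell mean expression over the set's genes present in
    the matrix."""
    present = [g for g in gene_set if g in matrix.gene_ids]
    if not present:
        raise ValueError(f"no gene of set {set_name!r} is present in the matrix")
    scores = matrix.data.loc[present].mean(axis=0)
    return CellSetScore(scores.rename(set_name or None), set_name, len(present))


def score_correlation(score_a: CellSetScore, score_b: CellSetScore,
                      method: str = "pearson"):
    """Correlation between two per-cell scores over their shared cells.

    Returns ``(coefficient, p_value, n)``; cells missing from either score
    are dropped.  Zero variance on either side yields NaN with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    shared = score_a.scores.index.intersection(score_b.scores.index)
    n = len(shared)
    if n < 3:
        raise ValueError(f"need at least 3 shared cells, got {n}")
    a = score_a.scores.loc[shared].to_numpy()
    b = score_b.scores.loc[shared].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in a score; correlation undefined")
        return float("nan"), float("nan"), n
    if method == "pearson":
        res = scipy.stats.pearsonr(a, b)
    else:
        res = scipy.stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue), n


def pairwise_gene_correlations(matrix: ExpressionMatrix, set_a, set_b,
                               cells_subset=None):
    """Pearson correlation for every gene pair across two sets.

    Returns ``(corr_matrix, fraction_positive)``; constant gene rows are
    excluded with a warning.  All (a, b) pairs enter the summary, including
    identical genes when the sets overlap."""
    sub = matrix if cells_subset is None else matrix.subset_cells(cells_subset)
    ga = [g for g in set_a if g in sub.gene_ids]
    gb = [g for g in set_b if g in sub.gene_ids]
    if not ga or not gb:
        raise ValueError("a gene set is empty after intersection with the matrix")
    data = sub.data
    sd = data.std(axis=1)
    const = sd.index[sd == 0]
    if len(const) and (set(const) & (set(ga) | set(gb))):
        warnings.warn(f"constant genes excluded: {sorted(set(const) & (set(ga) | set(gb)))[:10]}")
        ga = [g for g in ga if g not in set(const)]
        gb = [g for g in gb if g not in set(const)]
        if not ga or not gb:
            raise ValueError("all genes constant; no correlations defined")
    union = list(dict.fromkeys(ga + gb))
    C = np.corrcoef(data.loc[union].to_numpy())
    C = pd.DataFrame(C, index=union, columns=union).loc[ga, gb]
    frac_pos = float((C.to_numpy() > 0).mean())
    return C, frac_pos


def relative_mutual_information(labels_a, labels_b) -> float:
    """I(A;B) / min(H(A), H(B)) with natural-log entropies.

    1 when one partition determines the other (including the degenerate case
    of a single-cluster labeling, flagged with a warning); ~0 for independent
    labelings.  Invariant to renaming labels and symmetric in its arguments.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same cells")
    if isinstance(labels_b, pd.Series) and isinstance(labels_a, pd.Series):
        if not a.index.equals(b.index):
            b = b.reindex(a.index)
            if b.isna().any():
                raise ValueError("labelings must cover the same cells")
    h_a = scipy.stats.entropy(a.value_counts().to_numpy())
    h_b = scipy.stats.entropy(b.value_counts().to_numpy())
    h_min = min(h_a, h_b)
    if h_min == 0:
        warnings.warn("single-cluster labeling: agreement defined as 1")
        return 1.0
    mi = mutual_info_score(a.to_numpy(), b.to_numpy())
    return float(np.clip(mi / h_min, 0.0, 1.0))
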