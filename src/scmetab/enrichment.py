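"""Gene set enrichment analysis (GSEA) on ranked gene lists.

Implements the weighted Kolmogorov–Smirnov running-sum enrichment score, a
pre-ranked mode and a two-class mode with the difference-of-class-means
ranking metric.  Significance in both modes uses gene-set permutation: the
null is built from random gene sets of matched size drawn from the ranked
universe.  NES normalizes the observed ES by the mean magnitude of same-sign
null ES values; the p-value is the add-one-smoothed fraction of same-sign
null ES at least as extreme.

Ties in ranking scores are broken lexicographically by gene id so runs are
reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix, GeneSetCollection


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_genes_in_set_used: int

    def __post_init__(self) -> None:
        if np.isfinite(self.es) and abs(self.es) > 1 + 1e-12:
            raise ValueError(f"|ES| must be <= 1, got {self.es}")


def results_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": r.set_name, "es": r.es, "nes": r.nes, "p_value": r.p_value,
        "size": r.n_genes_in_set_used, "leading_edge": ",".join(r.leading_edge),
    } for r in results])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _rank_descending(genes, scores) -> tuple[np.ndarray, np.ndarray]:
    genes = np.asarray(genes, dtype=object)
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((genes, -scores))
    return genes[order], scores[order]


def enrichment_score(ranked_genes, ranked_scores, gene_set,
                     weight_exponent: float = 1.0):
    """Weighted running-sum enrichment score on a descending-ranked list.

    Hits increment the running sum by |score|^exponent normalized by the sum
    over set members; misses decrement by 1/(N - n_hits).  Returns
    ``(es, running_sum)`` where es is the signed maximum deviation.  When all
    hit scores are zero the hit weights fall back to uniform (the
    exponent-zero limit).
    """
    ranked_genes = np.asarray(ranked_genes, dtype=object)
    ranked_scores = np.asarray(ranked_scores, dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked_genes), dtype=bool,
                      count=len(ranked_genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    N = len(ranked_genes)
    if N == n_hit:
        raise ValueError("gene set covers the whole ranked list; no misses to walk")
    w = np.abs(ranked_scores[hit]) ** weight_exponent
    total_w = w.sum()
    if total_w == 0:
        w = np.ones(n_hit)
        total_w = float(n_hit)
    steps = np.full(N, -1.0 / (N - n_hit))
    steps[hit] = w / total_w
    running = np.cumsum(steps)
    es = running[int(np.argmax(np.abs(running)))]
    return float(es), running


def _es_from_positions(pos: np.ndarray, w: np.ndarray, N: int) -> float:
    """ES from sorted hit positions (0-based) and their weights, in O(n_hit).

    Equivalent to :func:`enrichment_score`: between hits the walk declines
    linearly, so extrema occur right after a hit (peak) or right before the
    next hit (valley)."""
    n_hit = pos.size
    miss = 1.0 / (N - n_hit)
    total = w.sum()
    if total == 0:
        w = np.ones(n_hit)
        total = float(n_hit)
    cw = np.cumsum(w / total)
    i = np.arange(n_hit)
    peak = cw - miss * (pos - i)            # value at the hit position
    valley = np.concatenate(([0.0], cw[:-1])) - miss * (pos - i)  # just before
    # end-of-list value is 0; never exceeds the candidates in magnitude
    cand = np.empty(2 * n_hit)
    cand[0::2] = valley
    cand[1::2] = peak
    return float(cand[int(np.argmax(np.abs(cand)))])


def _leading_edge(ranked_genes: np.ndarray, running: np.ndarray,
                  hit: np.ndarray, es: float) -> list[str]:
    ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        mask = hit & (np.arange(len(ranked_genes)) <= ext)
    else:
        mask = hit & (np.arange(len(ranked_genes)) >= ext)
    return list(ranked_genes[mask])


# ---------------------------------------------------------------------------
# pre-ranked GSEA with gene-set permutation
# ---------------------------------------------------------------------------

def preranked_gsea(ranking, gene_sets: GeneSetCollection, n_perm: int = 1000,
                   set_min: int = 5, set_max: int = 500,
                   seed: int | None = None, weight_exponent: float = 1.0
                   ) -> list[GseaResult]:
    """GSEA on a pre-ranked gene list.

    ``ranking`` is a pandas Series gene -> score (any order; sorted descending
    internally, ties broken by gene id).  For each gene set intersected with
    the ranked universe and within ``[set_min, set_max]``, the null is built
    from ``n_perm`` random same-size gene sets drawn from the universe.
    Results are sorted by p-value then |NES| descending.
    """
    ranking = pd.Series(ranking)
    genes, scores = _rank_descending(ranking.index.to_numpy(), ranking.to_numpy())
    N = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    weights_full = np.abs(scores) ** weight_exponent
    rng = np.random.default_rng(seed)

    usable = []
    for name, members in gene_sets:
        pos = np.array(sorted(index[g] for g in members if g in index), dtype=int)
        if set_min <= pos.size <= set_max and pos.size < N:
            usable.append((name, pos))
    if not usable:
        warnings.warn("no gene set within size bounds overlaps the ranking")
        return []

    null_cache: dict[int, np.ndarray] = {}

    def null_for(m: int) -> np.ndarray:
        if m not in null_cache:
            es_null = np.empty(n_perm)
            for b in range(n_perm):
                p = np.sort(rng.choice(N, size=m, replace=False))
                es_null[b] = _es_from_positions(p, weights_full[p], N)
            null_cache[m] = es_null
        return null_cache[m]

    results = []
    for name, pos in usable:
        es, running = enrichment_score(
            genes, scores, [genes[i] for i in pos], weight_exponent)
        hit = np.zeros(N, dtype=bool)
        hit[pos] = True
        null = null_for(pos.size)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes, p = float("nan"), 1.0
        else:
            denom = np.abs(null[same]).mean()
            nes = es / denom if denom > 0 else float("nan")
            p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        results.append(GseaResult(name, es, nes, p,
                                  _leading_edge(genes, running, hit, es),
                                  int(pos.size)))
    results.sort(key=lambda r: (r.p_value, -abs(r.nes) if np.isfinite(r.nes) else 0.0,
                                r.set_name))
    return results


def two_class_gsea(matrix: ExpressionMatrix, class_labels, gene_sets: GeneSetCollection,
                   n_perm: int = 1000, set_min: int = 5, set_max: int = 500,
                   seed: int | None = None, weight_exponent: float = 1.0,
                   class_order=None) -> list[GseaResult]:
    """Two-class GSEA with the difference-of-class-means ranking metric.

    Genes are ranked by (mean in class 1) - (mean in class 2) on the log2
    expression values, then scored exactly like :func:`preranked_gsea` with
    gene-set permutation.  ``class_order`` fixes which class is "class 1"
    (default: lexicographically sorted unique labels).
    """
    class_labels = pd.Series(class_labels)
    labels = class_labels.reindex(matrix.cell_ids)
    if labels.isna().any():
        raise ValueError("every matrix cell needs a class label")
    uniq = sorted(labels.unique()) if class_order is None else list(class_order)
    if len(uniq) != 2:
        raise ValueError(f"exactly two classes required, got {uniq}")
    a_cells = labels.index[labels == uniq[0]]
    b_cells = labels.index[labels == uniq[1]]
    if len(a_cells) < 3 or len(b_cells) < 3:
        raise ValueError("each class needs at least 3 cells")
    metric = matrix.data[a_cells].mean(axis=1) - matrix.data[b_cells].mean(axis=1)
    return preranked_gsea(metric, gene_sets, n_perm=n_perm, set_min=set_min,
                          set_max=set_max, seed=seed, weight_exponent=weight_exponent)
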