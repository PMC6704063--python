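"""Per-gene contribution to within-group expression variance.

The primary metric is the PCA loading score: run PCA with cells as
observations and genes as centered (not scaled) variables, keep the smallest
leading set of principal components that together explain at least a fraction
``variance_threshold`` (default 0.80) of the variance, and score each gene by
the sum of the absolute values of its loadings in those components.  CV and
SD are provided as alternative dispersion metrics.  Ranked gene lists feed
the pre-ranked GSEA in :mod:`scmetab.enrichment`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import GseaResult, preranked_gsea
from .io_preprocess import ExpressionMatrix, GeneSetCollection

_SV_TOL = 1e-12


@dataclass
class GeneVariabilityRanking:
    """Descending gene ranking by a variability score (ties broken by gene id)."""

    scores: pd.Series
    metric: str
    variance_threshold: float | None = None
    n_top_pcs: int | None = None

    def __post_init__(self) -> None:
        s = self.scores
        order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
        self.scores = s.iloc[order]

    @property
    def ranked_genes(self) -> pd.Index:
        return self.scores.index


def pca_gene_scores(matrix: ExpressionMatrix, cells_subset=None,
                    variance_threshold: float = 0.80,
                    scale: bool = False) -> GeneVariabilityRanking:
    """PCA loading score per gene over a cell subset.

    Intended for un-imputed log2(TPM+1) values.  Genes are centered
    (optionally scaled); the loading matrix columns are orthonormal
    eigenvectors of the gene-gene covariance, so a gene carried by a single
    component scores exactly 1.
    """
    sub = matrix if cells_subset is None else matrix.subset_cells(cells_subset)
    if sub.n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    X = sub.values.T  # cells x genes
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = np.divide(X, sd, out=np.zeros_like(X), where=sd > 0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    keep_sv = s > _SV_TOL * max(s[0], 1.0) if s.size else np.array([], dtype=bool)
    s = s[keep_sv]
    vt = vt[keep_sv]
    if s.size == 0:
        raise ValueError("matrix is constant over the cell subset; no variance")
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    n_pcs = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    n_pcs = min(n_pcs, len(s))
    scores = np.abs(vt[:n_pcs]).sum(axis=0)
    return GeneVariabilityRanking(pd.Series(scores, index=sub.gene_ids, name="pca_score"),
                                  "pca", variance_threshold, n_pcs)


def dispersion_scores(matrix: ExpressionMatrix, cells_subset=None,
                      metric: str = "sd") -> GeneVariabilityRanking:
    """Per-gene sample standard deviation (``sd``) or coefficient of variation
    (``cv`` = sd/mean; genes with mean 0 are undefined and excluded)."""
    if metric not in ("cv", "sd"):
        raise ValueError(f"metric must be 'cv' or 'sd', got {metric!r}")
    sub = matrix if cells_subset is None else matrix.subset_cells(cells_subset)
    sd = sub.data.std(axis=1, ddof=1)
    if metric == "sd":
        return GeneVariabilityRanking(sd.rename("sd"), "sd")
    mean = sub.data.mean(axis=1)
    ok = mean > 0
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} genes with zero mean excluded from CV")
    cv = (sd[ok] / mean[ok]).rename("cv")
    return GeneVariabilityRanking(cv, "cv")


def heterogeneity_enrichment(ranking: GeneVariabilityRanking,
                             gene_sets: GeneSetCollection, n_perm: int = 1000,
                             seed: int | None = None, **kwargs) -> list[GseaResult]:
    """Pre-ranked GSEA on a gene variability ranking (descending scores).

    Returns results sorted by p-value then normalized enrichment score."""
    if len(ranking.scores) == 0:
        raise ValueError("empty ranking")
    return preranked_gsea(ranking.scores, gene_sets, n_perm=n_perm, seed=seed, **kwargs)
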