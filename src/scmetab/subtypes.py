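"""Rule-based classification of tumor-microenvironment cell subtypes.

T cells are split on log2(TPM+1) marker expression: CD4 > 1 with CD8A < 1 is
CD4+; CD8A > 1 with CD4 < 1 is CD8+; both above 1 is excluded (putative
doublet); everything else is unassigned.  CD4+ cells with FOXP3 + CD25
(IL2RA) summing above 2 are regulatory T cells (Treg); CD4+ cells expressing
neither are helper T cells (Th).  Fibroblasts with FOS and VIM both below 1
are excluded; the rest are split by k-means (k=2) on a marker panel, and the
cluster with higher mean expression of the CAF-associated markers is labeled
CAF, the other myofibroblast.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_preprocess import ExpressionMatrix

#: gene-symbol synonyms accepted for rule markers (scRNA-seq matrices usually
#: carry IL2RA rather than the protein name CD25)
MARKER_SYNONYMS = {
    "CD25": ("CD25", "IL2RA"),
    "FOXP3": ("FOXP3", "FOX3P"),
}

#: default fibroblast marker panel (CAF- and myofibroblast-associated genes)
DEFAULT_FIBROBLAST_MARKERS = (
    "FAP", "THY1", "PDPN", "PDGFRA", "PDGFRL", "COL1A1", "COL1A2", "COL3A1",
    "MMP2", "DCN", "ACTA2", "MYL9", "MYLK", "TAGLN", "MCAM",
)
#: the CAF-associated subset used to decide which k-means cluster is the CAF one
DEFAULT_CAF_MARKERS = ("FAP", "THY1", "PDPN", "PDGFRA", "COL1A1", "COL1A2",
                       "COL3A1", "MMP2", "DCN")


@dataclass
class SubtypeAssignment:
    """cell_id -> subtype label, plus the rule that fired per cell."""

    labels: pd.Series
    rule_trace: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.rule_trace is None:
            self.rule_trace = pd.Series("", index=self.labels.index)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()

    def cells_with(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def _marker_row(matrix: ExpressionMatrix, marker: str) -> pd.Series:
    for name in MARKER_SYNONYMS.get(marker, (marker,)):
        if name in matrix.gene_ids:
            return matrix.data.loc[name]
    raise KeyError(f"marker gene {marker!r} absent from the matrix")


def classify_t_cells(matrix: ExpressionMatrix, threshold: float = 1.0
                     ) -> SubtypeAssignment:
    """CD4+/CD8+ assignment from CD4 and CD8A expression.

    Values exactly at the threshold fall into "unassigned"."""
    cd4 = _marker_row(matrix, "CD4")
    cd8a = _marker_row(matrix, "CD8A")
    labels = pd.Series("unassigned", index=matrix.cell_ids)
    trace = pd.Series(f"CD4<={threshold} or CD8A<={threshold} boundary",
                      index=matrix.cell_ids)
    is_cd4 = (cd4 > threshold) & (cd8a < threshold)
    is_cd8 = (cd8a > threshold) & (cd4 < threshold)
    both = (cd4 > threshold) & (cd8a > threshold)
    labels[is_cd4] = "CD4"
    trace[is_cd4] = f"CD4>{threshold} & CD8A<{threshold}"
    labels[is_cd8] = "CD8"
    trace[is_cd8] = f"CD8A>{threshold} & CD4<{threshold}"
    labels[both] = "excluded"
    trace[both] = f"CD4>{threshold} & CD8A>{threshold} (double positive)"
    return SubtypeAssignment(labels, trace)


def classify_cd4_subsets(matrix: ExpressionMatrix, cd4_cells,
                         sum_threshold: float = 2.0) -> SubtypeAssignment:
    """Treg/Th assignment within CD4+ cells from FOXP3 and CD25 (IL2RA).

    FOXP3 + CD25 above ``sum_threshold`` is Treg; both exactly zero is Th;
    anything in between is unassigned."""
    cd4_cells = pd.Index(cd4_cells)
    foxp3 = _marker_row(matrix, "FOXP3").loc[cd4_cells]
    cd25 = _marker_row(matrix, "CD25").loc[cd4_cells]
    labels = pd.Series("unassigned", index=cd4_cells)
    trace = pd.Series("intermediate FOXP3/CD25", index=cd4_cells)
    treg = (foxp3 + cd25) > sum_threshold
    th = (foxp3 == 0) & (cd25 == 0)
    labels[treg] = "Treg"
    trace[treg] = f"FOXP3+CD25>{sum_threshold}"
    labels[th] = "Th"
    trace[th] = "FOXP3=0 & CD25=0"
    return SubtypeAssignment(labels, trace)


def classify_fibroblasts(matrix: ExpressionMatrix, marker_genes=None,
                         caf_markers=None, seed: int | None = 0, k: int = 2,
                         exclusion_threshold: float = 1.0,
                         n_init: int = 10) -> SubtypeAssignment:
    """CAF/myofibroblast assignment of fibroblast cells.

    Cells with FOS and VIM both below ``exclusion_threshold`` are excluded;
    the remainder are clustered by k-means (``n_init`` restarts, fixed seed)
    on the marker-gene expression submatrix.  Cluster identity is decided by
    mean expression of the CAF-associated markers, so labels are invariant to
    cluster-index permutation.
    """
    marker_genes = list(marker_genes or DEFAULT_FIBROBLAST_MARKERS)
    caf_markers = list(caf_markers or DEFAULT_CAF_MARKERS)
    fos = _marker_row(matrix, "FOS")
    vim = _marker_row(matrix, "VIM")
    present = [g for g in marker_genes if g in matrix.gene_ids]
    if not present:
        raise KeyError(f"none of the marker genes {marker_genes} are in the matrix")
    caf_present = [g for g in caf_markers if g in present]
    if not caf_present:
        raise KeyError("no CAF-associated marker gene present in the matrix")
    excluded = (fos < exclusion_threshold) & (vim < exclusion_threshold)
    keep = matrix.cell_ids[~excluded.to_numpy()]
    if len(keep) == 0:
        raise ValueError("all cells excluded by the FOS/VIM filter")
    if len(keep) < 2 * k:
        raise ValueError(f"need at least {2 * k} cells after exclusion, got {len(keep)}")
    X = matrix.data.loc[present, keep].T.to_numpy()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    caf_expr = matrix.data.loc[caf_present, keep].mean(axis=0).to_numpy()
    cluster_caf_mean = np.array([caf_expr[km.labels_ == c].mean() for c in range(k)])
    caf_cluster = int(np.argmax(cluster_caf_mean))
    labels = pd.Series("excluded", index=matrix.cell_ids)
    trace = pd.Series(f"FOS<{exclusion_threshold} & VIM<{exclusion_threshold}",
                      index=matrix.cell_ids)
    cl = pd.Series(km.labels_, index=keep)
    labels[keep] = np.where(cl == caf_cluster, "CAF", "myofibroblast")
    trace[keep] = [f"kmeans cluster {c} ({'CAF' if c == caf_cluster else 'myofibroblast'} "
                   "by CAF-marker mean)" for c in cl]
    return SubtypeAssignment(labels, trace)
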