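"""Synthetic tumor-microenvironment expression data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* several cell types plus malignant cells assigned to tumors;
* log-normal base expression per gene with cell-level biological noise;
* planted pathway up-regulation (log2 fold-changes) per cell type;
* tumor-specific Gaussian expression shifts confined to malignant cells
  (a random 20% of genes per tumor);
* a per-cell latent factor (the "hypoxia" axis) that shifts designated gene
  sets proportionally to their loadings, coupling e.g. glycolysis and
  OXPHOS programs;
* dropout whose probability rises as underlying expression falls
  (logistic in log2 expression);
* per-cell library-size variation, applied before the final per-cell TPM
  renormalization (so it surfaces on the count scale, not the TPM scale).

Everything planted is recorded in a truth dictionary and fully reproducible
from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import (
    TPM_TOTAL,
    CellAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
)

#: fraction of genes receiving a tumor-specific shift in malignant cells
TUMOR_SHIFT_GENE_FRACTION = 0.20


@dataclass
class PlantedEffect:
    pathway: str
    cell_type: str
    log2_fc: float


@dataclass
class SimulationSpec:
    """Parameters of a synthetic dataset.

    Defaults give a mid-sized, moderately noisy dataset: 1000 genes, gene
    sets of 25 genes, per-gene log2 baselines ~ N(3, 1.5^2) (log-normal TPM
    scale), cell-level noise sd 0.5 log2 units, logistic dropout centered at
    log2 expression 1 with slope 1, and 20% per-cell library-size variation.
    """

    n_genes: int = 1000
    gene_set_sizes: dict[str, int] = field(default_factory=lambda: {
        f"PATHWAY_{i:02d}": 25 for i in range(10)})
    cell_types: dict[str, int] = field(default_factory=lambda: {
        "T_cell": 100, "B_cell": 100, "macrophage": 100})
    tumors: dict[str, int] = field(default_factory=lambda: {
        "tumor1": 100, "tumor2": 100})
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    tumor_effect_sd: float = 0.0      # log2 units, malignant cells only
    latent_loadings: dict[str, float] = field(default_factory=dict)
    dropout_midpoint: float | None = None   # log2 expression at 50% dropout
    dropout_slope: float = 1.0
    library_size_sd: float = 0.2      # sd of log library-size factor
    noise_sd: float = 0.5             # cell-level biological noise, log2 units
    base_log2_mean: float = 3.0
    base_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name, n in {**self.cell_types, **self.tumors}.items():
            if n < 1:
                raise ValueError(f"group {name!r} must have >= 1 cells")
        for name, size in self.gene_set_sizes.items():
            if not (1 <= size <= self.n_genes):
                raise ValueError(f"gene set {name!r} size out of range")
        for eff in self.planted_effects:
            if not np.isfinite(eff.log2_fc):
                raise ValueError("planted fold-changes must be finite")
            if eff.pathway not in self.gene_set_sizes:
                raise ValueError(f"planted effect targets unknown pathway {eff.pathway!r}")
        for name in self.latent_loadings:
            if name not in self.gene_set_sizes:
                raise ValueError(f"latent loading targets unknown pathway {name!r}")


def _dropout_probability(log2_expr: np.ndarray, midpoint: float, slope: float
                         ) -> np.ndarray:
    """Logistic dropout curve, decreasing in expression."""
    return 1.0 / (1.0 + np.exp(slope * (log2_expr - midpoint)))


def generate(spec: SimulationSpec):
    """Generate ``(matrix [log2tpm1], annotation, gene_sets, truth)``.

    The truth record stores every planted parameter: set membership, the
    per-tumor shifted genes and shifts, latent factor values per cell,
    library factors and the dropout mask.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])

    sets = {name: sorted(rng.choice(spec.n_genes, size=size, replace=False))
            for name, size in spec.gene_set_sizes.items()}
    gene_sets = GeneSetCollection({n: [genes[i] for i in idx] for n, idx in sets.items()})

    # cells: non-malignant types spread round-robin over tumors, malignant per tumor
    cell_ids, cell_type, tumor_id, malignant = [], [], [], []
    tumor_names = list(spec.tumors) or ["tumor0"]
    for ct, n in spec.cell_types.items():
        for i in range(n):
            cell_ids.append(f"{ct}_{i:04d}")
            cell_type.append(ct)
            tumor_id.append(tumor_names[i % len(tumor_names)])
            malignant.append(False)
    for tum, n in spec.tumors.items():
        for i in range(n):
            cell_ids.append(f"{tum}_mal_{i:04d}")
            cell_type.append("malignant")
            tumor_id.append(tum)
            malignant.append(True)
    n_cells = len(cell_ids)
    ann = CellAnnotation(pd.DataFrame(
        {"tumor_id": tumor_id, "cell_type": cell_type, "malignant": malignant},
        index=pd.Index(cell_ids, name="cell_id")))
    ct_arr = np.array(cell_type)
    tum_arr = np.array(tumor_id)
    mal_arr = np.array(malignant)

    baseline = rng.normal(spec.base_log2_mean, spec.base_log2_sd, spec.n_genes)
    L = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, n_cells))

    for eff in spec.planted_effects:
        cols = np.flatnonzero(ct_arr == eff.cell_type)
        if cols.size == 0:
            raise ValueError(f"planted effect targets unknown cell type {eff.cell_type!r}")
        L[np.ix_(sets[eff.pathway], cols)] += eff.log2_fc

    tumor_shifts: dict[str, dict] = {}
    if spec.tumor_effect_sd > 0:
        n_shift = max(1, int(round(TUMOR_SHIFT_GENE_FRACTION * spec.n_genes)))
        for tum in spec.tumors:
            rows = rng.choice(spec.n_genes, size=n_shift, replace=False)
            shifts = rng.normal(0.0, spec.tumor_effect_sd, n_shift)
            cols = np.flatnonzero((tum_arr == tum) & mal_arr)
            L[np.ix_(rows, cols)] += shifts[:, None]
            tumor_shifts[tum] = {"genes": [genes[i] for i in rows],
                                 "shifts": shifts.copy()}

    latent = rng.normal(0.0, 1.0, n_cells)
    for name, loading in spec.latent_loadings.items():
        L[sets[name], :] += loading * latent[None, :]

    tpm = np.exp2(L)

    dropout_mask = np.zeros_like(tpm, dtype=bool)
    if spec.dropout_midpoint is not None:
        p = _dropout_probability(L, spec.dropout_midpoint, spec.dropout_slope)
        dropout_mask = rng.random(tpm.shape) < p
        tpm = np.where(dropout_mask, 0.0, tpm)

    lib = np.exp(rng.normal(0.0, spec.library_size_sd, n_cells)) \
        if spec.library_size_sd > 0 else np.ones(n_cells)
    tpm = tpm * lib[None, :]

    totals = tpm.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a cell lost all expression to dropout; relax the dropout curve")
    tpm = tpm / totals[None, :] * TPM_TOTAL

    matrix = ExpressionMatrix(
        pd.DataFrame(np.log2(tpm + 1.0), index=genes, columns=cell_ids), "log2tpm1")
    truth = {
        "spec": spec,
        "set_members": {n: [genes[i] for i in idx] for n, idx in sets.items()},
        "planted_effects": list(spec.planted_effects),
        "tumor_shifts": tumor_shifts,
        "latent": pd.Series(latent, index=cell_ids),
        "latent_loadings": dict(spec.latent_loadings),
        "library_factors": pd.Series(lib, index=cell_ids),
        "dropout_mask": dropout_mask,
        "baseline_log2": pd.Series(baseline, index=genes),
    }
    return matrix, ann, gene_sets, truth


def generate_null(n_genes: int, n_cells: int, n_types: int, seed: int,
                  n_sets: int = 50, set_size: int = 20, noise_sd: float = 0.5):
    """Structure-free data for type-I-error calibration: all cells i.i.d.,
    cell-type labels assigned round-robin, random gene sets."""
    spec = SimulationSpec(
        n_genes=n_genes,
        gene_set_sizes={f"NULLSET_{i:03d}": set_size for i in range(n_sets)},
        cell_types={"only": n_cells},
        tumors={},
        library_size_sd=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    matrix, ann, gene_sets, truth = generate(spec)
    labels = [f"type{i % n_types}" for i in range(n_cells)]
    table = ann.table.copy()
    table["cell_type"] = labels
    return matrix, CellAnnotation(table), gene_sets, truth


def generate_counts_with_factors(n_genes: int = 500, n_cells: int = 200,
                                 factor_sigma: float = 0.25, seed: int = 0,
                                 mean_depth: float = 20.0):
    """Poisson counts with known per-cell size factors drawn from
    LogNormal(0, ``factor_sigma``); used to benchmark size-factor recovery.

    Returns ``(counts_matrix, true_factors)`` with the truth rescaled to
    mean 1."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(mean_depth), 1.0, n_genes))
    factors = np.exp(rng.normal(0.0, factor_sigma, n_cells))
    lam = base[:, None] * factors[None, :]
    counts = rng.poisson(lam).astype(float)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cells = [f"c{i:04d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=cells), "counts")
    truth = pd.Series(factors / factors.mean(), index=cells)
    return matrix, truth
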