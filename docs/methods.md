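# Methods

This note documents the statistical model behind each `scmetab` stage, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic test bed does and does not establish about real data.

## Data model and conventions

Expression matrices are genes × cells with a declared unit: `log2tpm1`
(log2(TPM+1), the working unit of all scoring), `tpm`, or `counts`
(pseudo-counts reconstructed as TPM × gene length are accepted everywhere;
no estimator assumes integers). Matrices are dense pandas DataFrames —
the package targets plate-based scRNA-seq scale (10³–10⁴ cells), not
droplet-scale sparsity. Cell annotations carry tumor of origin, cell type
and a malignant flag. Gene sets come from GMT files; genes absent from the
matrix are dropped from sets with a warning at load time.

Group-size filtering removes under-populated groups jointly: malignant
cells are grouped by tumor, non-malignant cells by cell type, and any group
under `min_cells` (default 50) is dropped. A tumor's non-malignant cells
survive removal of its malignant group, because the two groupings answer
different questions (per-patient malignant programs vs per-lineage
programs).

## Dropout imputation

Imputation is restricted to genes with dropout rate above a threshold
(default 0.5): well-detected genes are left bit-identical to guard against
over-imputation, and nonzero entries are never modified. The default
`neighbor_mean` method replaces a zero by the mean of the gene over the
cell's k nearest neighbors (default 10), with neighborhoods computed by
correlation distance over the well-detected genes, within the same cell
type when an annotation is given. The imputation stage is deliberately
pluggable: the contract (mask preservation, non-negativity) is what the
rest of the pipeline relies on, not the particular estimator, so a
heavier model-based imputer can be swapped in without touching anything
downstream.

## Pathway activity and its permutation test

The score p<sub>t,j</sub> is a weighted average of relative expression
(README, "The pathway activity score"). Choices the definition leaves open:

- **Outlier pool.** The 25th/75th percentiles of the outlier rule are taken
  over the pathway's member-gene r values pooled across all cell types, and
  a flagged gene is removed from that pathway in *all* cell types. This
  keeps a pathway's scores comparable across types; per-type removal would
  change the gene set per column.
- **Weights** w<sub>i</sub> are computed from the same gene-set collection
  that is being scored, before intersection with the matrix, so a gene's
  weight does not depend on which genes happened to be measured.
- A pathway whose members are all absent or all flagged gets an undefined
  (NaN) score, never 0 — zero is a meaningful activity value.

The permutation test globally shuffles cell-type labels and recomputes the
entire mean → relative-expression → score chain, outlier rule included, per
shuffle. The tail is chosen by the observed score's direction: null scores
larger than an observed score above 1, smaller than one below 1. Two
estimator details:

- **Calibration.** The raw directional fraction is not a calibrated
  p-value: under the null it is approximately Uniform(0, ½), so thresholding
  it at α rejects ~2α of true nulls. The default estimator therefore
  doubles the directional tail (capped at 1), which makes the p-value
  uniform under label exchangeability — the acceptance suite verifies a
  rejection rate within [0.03, 0.07] at α = 0.05 and KS uniformity. The raw
  fraction remains available (`tail="observed"`) for comparability with
  analyses that used it; its effective size at a nominal α is ~2α.
- **Smoothing.** p = (1 + x)/(1 + n) keeps p strictly positive with n
  permutations; `smoothing=False` recovers the plain fraction. Scores
  exactly equal to 1 get p = 1 by convention.

Defaults: 5000 permutations for single-cell data, 1000 for bulk sample
groups (`bulk_group_activity`, which reuses the identical machinery with
sample groups in place of cell types).

Because TPM is compositional and relative expression compares each type to
the across-type average, a genuine up-regulation in one type necessarily
produces small opposite shifts elsewhere; with enough cells those shifts
can reach significance. This is a property of the statistic, not an
artifact of the implementation.

## Normalization evaluation

All four size-factor estimators operate on "reference genes" only — genes
with dropout rate below 0.75 — and accept non-integer pseudo-counts:

- **RLE**: median across reference genes of count / per-gene geometric
  mean (genes positive in every cell); factors are rescaled to geometric
  mean 1.
- **TMM**: weighted trimmed mean of per-gene log-ratios against a reference
  cell (the cell whose upper quartile of count/library is closest to the
  mean), trimming 30% on M and 5% on A, with inverse-variance precision
  weights; the size factor is the TMM normalization factor times library
  size, rescaled to mean 1.
- **Upper quartile**: 75th percentile of nonzero reference-gene counts per
  cell, mean 1.
- **Deconvolution**: within each cell type, cells are placed on a ring
  ordered smoothly by library size (ties broken by cell id so the result
  is invariant to input order), pools of consecutive cells (sizes
  20/40/60/80/100, capped at the group size) are summed, each pool sum is
  compared to the group's average profile by a median ratio, and the linear
  system "pool factor = sum of member factors" is solved by least squares.
  The ring system alone is rank-deficient for many group sizes (all window
  sizes share circulant null spaces), so low-weight (0.01) anchor equations
  tying each cell to its library-size factor are part of the system; a
  still-deficient system raises an error suggesting larger pools. Groups
  are then rescaled to a common reference via the median ratio of the
  group mean profile to the overall mean profile.

Method selection: each method's normalized output is scored by the mean
two-sample Kolmogorov–Smirnov statistic of log relative expression between
all cell-type pairs; the method minimizing the score wins. KS was chosen as
the distribution-difference metric because it is distribution-free,
symmetric and scale-insensitive. The reference-gene filter is applied
uniformly to all four methods.

## Heterogeneity ranking

PCA runs on un-imputed log2(TPM+1) values with cells as observations and
genes as centered, unscaled variables (centering without scaling preserves
the contribution of high-variance genes, matching standard PCA practice for
this metric). The variance fraction for the ≥80% rule uses the PC
eigenvalues of the centered data. Loadings are orthonormal eigenvectors of
the gene-gene covariance, so sign ambiguity is irrelevant to the
absolute-value score and a gene carried by a single component scores
exactly 1. Components with singular values below 10⁻¹² of the largest are
discarded (relevant only for `variance_threshold=1.0` on rank-deficient
data). CV (sd/mean) and SD (sample sd, ddof 1) are provided as alternative
metrics; CV systematically promotes low-abundance genes, which the tests
demonstrate as a rank-correlation property.

## GSEA

The enrichment score is the signed maximum deviation of the weighted
running sum: hits add |score|^exponent normalized by the sum over set
members (exponent 1 by default; if all hit scores are zero the weights fall
back to uniform, the exponent-0 limit), misses subtract 1/(N − n_hits).
Ranking ties are broken lexicographically by gene id for reproducibility.
An O(n_hits) closed form evaluated only at hit-adjacent positions is used
in permutation loops and is tested to 10⁻¹² against the explicit walk.

The null in both pre-ranked and two-class mode is gene-set permutation:
random same-size sets drawn from the ranked universe. NES divides the
observed ES by the mean |ES| of same-sign null draws; the p-value is the
add-one-smoothed fraction of same-sign null ES at least as extreme — this
sign-conditioning makes the p-value uniform under the null, which the test
suite checks. The two-class ranking metric is the difference of class
means on log2 values; swapping the classes negates every ES exactly. Sets
outside [set_min, set_max] = [5, 500] after intersection are omitted.

## Subtype rules

T cells: CD4 > 1 and CD8A < 1 → CD4+; CD8A > 1 and CD4 < 1 → CD8+; both
above 1 → excluded as putative doublets; values exactly at the threshold
fall to "unassigned" — every cell receives exactly one label, and the rule
that fired is recorded per cell. CD4+ cells: FOXP3 + CD25 > 2 → Treg;
both exactly zero → Th. CD25 is accepted under either symbol CD25 or IL2RA
(matrices typically carry the gene symbol IL2RA). Fibroblasts: cells with
FOS and VIM both < 1 are excluded, the rest are clustered by k-means
(k = 2, 10 restarts, fixed seed) on a marker panel; the cluster with higher
mean expression of the CAF-associated markers is labeled CAF, making the
labeling invariant to cluster-index permutation. The default marker panel
(FAP, THY1, PDPN, PDGFRA, COL1A1/2, COL3A1, MMP2, DCN vs ACTA2, MYL9,
MYLK, TAGLN, MCAM) is a standard CAF/myofibroblast split and is fully
user-overridable.

## Signature scores and agreement

Per-cell program scores are unweighted means of log2(TPM+1) over the set's
present genes — no per-cell re-normalization, so scores are linear in the
matrix (an exactness the tests exploit). Correlations are standard Pearson
or Spearman with two-sided p-values; zero-variance inputs yield NaN with a
warning rather than an exception. Cluster agreement is relative mutual
information I(A;B)/min(H(A), H(B)) with natural-log entropies, clipped to
[0,1]: min-entropy normalization makes nested refinements score exactly 1,
which is the behavior wanted when comparing a fine clustering to a coarse
one; degenerate single-cluster labelings are defined as agreement 1 with a
warning.

## Synthetic data

`generate` draws per-gene log2 baselines from N(3, 1.5²) (log-normal TPM
scale spanning ~4 orders of magnitude) and adds, in log2 space: cell-level
noise (sd 0.5 by default), planted pathway effects (fixed log2 fold-changes
for a set's genes in a target cell type), tumor-specific shifts for
malignant cells (Gaussian with configurable sd on a random 20% of genes
per tumor), and a per-cell standard-normal latent factor scaled by each
loaded set's loading — the device that couples glycolysis-like and
OXPHOS-like programs through a shared "hypoxia" axis. Zeros are then
introduced with logistic probability decreasing in expression (midpoint and
slope configurable; off by default), a log-normal library factor (sd 0.2)
scales each cell, and columns are renormalized to TPM before logging.

Because of the final TPM renormalization, planted fold-changes are exactly
recoverable from noiseless data only through ratios that cancel the
per-cell scale — the tests verify the double ratio
(E<sub>planted,A</sub>/E<sub>planted,B</sub>) /
(E<sub>unplanted,A</sub>/E<sub>unplanted,B</sub>) = 2^Δ exactly — and
approximately through the full pathway-activity pipeline.

`generate_null` produces i.i.d. cells with round-robin type labels for
type-I-error calibration. `generate_counts_with_factors` produces Poisson
counts with known LogNormal per-cell size factors for normalization
benchmarks.

What the generator does *not* emulate: count-level overdispersion beyond
Poisson (expression is log-normal at the TPM level), doublets, batch
effects, ambient RNA, or gene-gene correlation structure beyond the planted
sets and latent factor. Passing tests therefore establish the estimators'
correctness and calibration under a clean generative model, not robustness
to every artifact of real scRNA-seq data.

## Problem sizes and determinism

The validation experiments use desk-scale problems chosen to make the
measured quantities stable: 100 random matrices for the exact
relative-expression identity; 200 cells × 4 types × 100 pathways × 200
permutations for null calibration (400 p-values); 50 replicates of a
300-gene, 200-cell, 20-pathway dataset with 500 permutations for detection
power; 100 random instances for the enrichment-score oracle; 20×50
matrices for the PCA oracle; 200 cells for deconvolution recovery; a
0.25-step grid over [0, 3]² for the subtype rules; 20 replicates for
heterogeneity enrichment. Every stochastic stage takes an explicit seed,
`run_pipeline` serializes the resolved configuration next to its outputs,
and reruns are byte-identical.

## Known limitations

- Dense matrices bound the practical scale to plate-based datasets.
- The neighbor-mean imputer is intentionally simple; it preserves the
  contract but not the model-based behavior of heavier imputers.
- The raw directional permutation p-value (available behind a flag) is
  anti-conservative by a factor ~2, as discussed above.
- Deconvolution factors for very small cell-type groups lean on the
  library-size anchors; groups below ~20 cells get factors close to
  library-size normalization.
- GSEA significance uses gene-set permutation only; phenotype permutation
  (which preserves gene-gene correlation under the null) is not
  implemented.
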