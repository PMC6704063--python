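"""Run configuration and the end-to-end pipeline.

The pipeline order mirrors the analysis workflow: read + group-size filter ->
dropout imputation -> (optional) size-factor normalization -> cell-type
pathway activity with permutation significance -> heterogeneity ranking +
enrichment -> subtype classification (where marker genes exist) -> signature
score correlations.  Outputs are plain TSV files with a leading schema
comment line; the resolved configuration (seeds included) is serialized next
to them, so a rerun with the same config is byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    enrichment,
    heterogeneity,
    io_preprocess,
    normalization,
    pathway_activity,
    signatures,
    subtypes,
)

log = logging.getLogger("scmetab")


@dataclass
class RunConfig:
    matrix_path: str
    annotation_path: str
    gmt_path: str
    output_dir: str
    lengths_path: str | None = None
    unit: str = "log2tpm1"
    min_cells: int = 50
    impute: bool = True
    dropout_threshold: float = 0.5
    normalization_method: str | None = None   # needs lengths + counts/tpm input
    reference_dropout_max: float = 0.75
    n_perm_activity: int = 5000
    n_perm_gsea: int = 1000
    seed: int = 0
    heterogeneity_metric: str = "pca"
    heterogeneity_group: str = "tumor_id"
    variance_threshold: float = 0.80
    correlate_sets: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("matrix_path", "annotation_path", "gmt_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p!r}")
        if self.lengths_path and not Path(self.lengths_path).exists():
            raise FileNotFoundError(f"lengths_path does not exist: {self.lengths_path!r}")
        if self.normalization_method and not self.lengths_path:
            raise ValueError("normalization requires a gene-length table")
        if self.heterogeneity_metric not in ("pca", "cv", "sd"):
            raise ValueError(f"unknown heterogeneity metric {self.heterogeneity_metric!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_tsv(df: pd.DataFrame, path, schema: str) -> None:
    """TSV with a leading '#' schema line (diff-friendly outputs)."""
    with open(path, "w") as fh:
        fh.write(f"# {schema}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "read_inputs"
        try:
            matrix, ann, gene_sets, lengths = io_preprocess.read_inputs(
                config.matrix_path, config.annotation_path, config.gmt_path,
                config.lengths_path, unit=config.unit)
            log.info("read %d genes x %d cells, %d gene sets",
                     matrix.n_genes, matrix.n_cells, len(gene_sets))
            stage = "filter_small_groups"
            matrix, ann = io_preprocess.filter_small_groups(matrix, ann, config.min_cells)
            log.info("%d cells after min_cells=%d filter", matrix.n_cells, config.min_cells)

            unimputed = matrix  # PCA heterogeneity runs without imputation
            stage = "impute_dropouts"
            if config.impute and matrix.unit in ("log2tpm1", "tpm"):
                matrix = io_preprocess.impute_dropouts(
                    matrix, config.dropout_threshold, annotation=ann)

            stage = "normalization"
            if config.normalization_method:
                counts = (matrix if matrix.unit == "counts" else
                          normalization.tpm_counts_convert(matrix, lengths, "to_counts"))
                sf = normalization.size_factors(
                    counts, config.normalization_method, annotation=ann,
                    reference_dropout_max=config.reference_dropout_max)
                matrix = normalization.apply_size_factors(counts, sf, lengths)
                pd.DataFrame({"cell_id": sf.factors.index, "factor": sf.factors.values}) \
                    .pipe(write_tsv, out / "size_factors.tsv", "cell_id\tfactor")

            stage = "pathway_activity"
            activity = pathway_activity.permutation_test(
                matrix, ann, gene_sets, n_perm=config.n_perm_activity, seed=config.seed)
            write_tsv(activity.to_frame(), out / "pathway_activity.tsv",
                      "pathway\tgroup\tscore\tp_value\tn_genes_used")

            stage = "heterogeneity"
            groups = ann.table[config.heterogeneity_group].unique()
            het_rows, enr_rows = [], []
            for g in groups:
                cells = ann.table.index[ann.table[config.heterogeneity_group] == g]
                if len(cells) < 3:
                    continue
                if config.heterogeneity_metric == "pca":
                    ranking = heterogeneity.pca_gene_scores(
                        unimputed, cells, config.variance_threshold)
                else:
                    ranking = heterogeneity.dispersion_scores(
                        unimputed, cells, config.heterogeneity_metric)
                for gene, score in ranking.scores.items():
                    het_rows.append({"group": g, "gene": gene, "score": score})
                for res in heterogeneity.heterogeneity_enrichment(
                        ranking, gene_sets, n_perm=config.n_perm_gsea, seed=config.seed):
                    enr_rows.append({"group": g, "set": res.set_name, "es": res.es,
                                     "nes": res.nes, "p_value": res.p_value})
            write_tsv(pd.DataFrame(het_rows), out / "heterogeneity_ranking.tsv",
                      "group\tgene\tscore")
            write_tsv(pd.DataFrame(enr_rows), out / "heterogeneity_enrichment.tsv",
                      "group\tset\tes\tnes\tp_value")

            stage = "subtypes"
            sub_rows = []
            t_cells = ann.table.index[ann.table["cell_type"].str.lower()
                                      .str.contains("t_cell|t cell|tcell", regex=True)]
            if len(t_cells) and all(
                    any(s in matrix.gene_ids for s in subtypes.MARKER_SYNONYMS.get(m, (m,)))
                    for m in ("CD4", "CD8A")):
                tc = subtypes.classify_t_cells(matrix.subset_cells(t_cells))
                for cell, lab in tc.labels.items():
                    sub_rows.append({"cell_id": cell, "label": lab})
            if sub_rows:
                write_tsv(pd.DataFrame(sub_rows), out / "subtypes.tsv", "cell_id\tlabel")
            else:
                log.info("subtype stage skipped: no T cells or marker genes absent")

            stage = "correlations"
            corr_rows = []
            names = config.correlate_sets or gene_sets.names[:3]
            scored = {n: signatures.cell_set_score(matrix, gene_sets.sets[n], n)
                      for n in names if n in gene_sets.sets}
            keys = list(scored)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    r, p, n = signatures.score_correlation(scored[keys[i]], scored[keys[j]])
                    corr_rows.append({"set_a": keys[i], "set_b": keys[j],
                                      "pearson_r": r, "p_value": p, "n_cells": n})
            write_tsv(pd.DataFrame(corr_rows), out / "signature_correlations.tsv",
                      "set_a\tset_b\tpearson_r\tp_value\tn_cells")

            config.to_yaml(out / "resolved_config.yaml")
            log.info("pipeline complete")
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            log.error("stage %s failed: %s", stage, exc)
            raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
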