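"""End-to-end orchestration: PSM tables -> quantification -> preprocessing
-> differential expression -> enrichment, with provenance logging.

Every stage's feature counts are logged, all outputs are plain TSV/CSV,
and a provenance JSON (parameters, package version, SHA-256 input digests)
accompanies the results so a run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .quantify import ImpurityMatrix, quantify_plexes
from .preprocess import (
    correct_batch,
    filter_missingness,
    groups_from_design,
    impute_knn,
    pca,
    qc_metrics,
    rollup_peptide_to_protein,
)
from .linear_model import run_comparisons, select_regulated
from .enrichment import collapse_redundant, fisher_enrichment, read_gmt

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters.

    Defaults are the study's stated parameters: missingness threshold
    0.35, kNN k=2, trimmed-mean trim 0.2, fold-change gate 1.3, p < 0.05,
    minimum term overlap 2, calibrant channels 129C/130N/130C/131.
    """

    psm_paths: list[str] = field(default_factory=list)
    design_path: str = ""
    impurity_path: str | None = None
    gmt_paths: dict[str, str] = field(default_factory=dict)  # ontology tag -> path
    output_dir: str = "results"
    missingness_threshold: float = 0.35
    knn_k: int = 2
    trim: float = 0.2
    fc_threshold: float = 1.3
    p_threshold: float = 0.05
    min_overlap: int = 2
    use_adjusted_p: bool = False
    moderation: bool = True
    collapse_redundant_terms: bool = False
    exclude_qc_outliers: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Bundle of every pipeline product."""

    peptide_matrix: pd.DataFrame
    peptide_annotations: pd.DataFrame
    protein_matrix: pd.DataFrame
    removal_log: pd.DataFrame
    qc_table: pd.DataFrame
    pca_variance_explained: list[float]
    de_results: dict
    regulated: dict
    enrichment: dict
    provenance: dict


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all outputs under
    ``config.output_dir``. Deterministic given identical inputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = pd.read_csv(config.design_path)
    psm_tables = {}
    for p in sorted(config.psm_paths):
        t = pd.read_csv(p)
        plex = str(t["plex_id"].iloc[0])
        psm_tables[plex] = t
    impurity = (
        ImpurityMatrix.from_csv(config.impurity_path) if config.impurity_path else None
    )

    # quantification: PSM -> peptide x sample log2 calibrator ratios
    matrix, annotations = quantify_plexes(psm_tables, design, impurity)
    matrix.to_csv(outdir / "peptide_ratios.tsv", sep="\t")

    groups = groups_from_design(design)
    filtered, removal_log = filter_missingness(
        matrix, groups, config.missingness_threshold
    )
    removal_log.to_csv(outdir / "removal_log.tsv", sep="\t", index=False)
    imputed = impute_knn(filtered, groups, config.knn_k)

    qc = qc_metrics(imputed)
    qc.table.to_csv(outdir / "qc_report.tsv", sep="\t")
    work = imputed
    if config.exclude_qc_outliers and qc.outliers:
        logger.warning("excluding QC outlier samples: %s", qc.outliers)
        work = imputed.drop(columns=qc.outliers)

    corrected = correct_batch(work, groups)
    corrected.to_csv(outdir / "peptide_ratios_corrected.tsv", sep="\t")

    # corrected values are for visualisation (PCA, exported matrices);
    # inference runs on the uncorrected rollup with batch in the model,
    # which keeps residual degrees of freedom honest
    protein_corrected = rollup_peptide_to_protein(corrected, annotations, config.trim)
    protein_corrected = protein_corrected.dropna(how="any")
    protein_corrected.to_csv(outdir / "protein_ratios.tsv", sep="\t")

    protein = rollup_peptide_to_protein(work, annotations, config.trim)
    protein = protein.dropna(how="any")

    pc = pca(corrected)
    pd.DataFrame(
        {"variance_explained": pc.variance_explained},
        index=pc.scores.columns,
    ).to_csv(outdir / "pca_variance.tsv", sep="\t")
    pc.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")

    de_results = run_comparisons(protein, design, moderate=config.moderation)
    regulated = {}
    for name, res in de_results.items():
        res.to_report().to_csv(outdir / f"de_{name}.tsv", sep="\t")
        reg = res.regulated(
            config.fc_threshold, config.p_threshold, config.use_adjusted_p
        )
        regulated[name] = reg
        reg.to_csv(outdir / f"regulated_{name}.tsv", sep="\t")
        logger.info("%s: %d regulated of %d genes", name, reg.shape[0], res.table.shape[0])

    enrichment = {}
    if config.gmt_paths:
        sets = []
        for ontology, path in sorted(config.gmt_paths.items()):
            sets.extend(read_gmt(path, ontology=ontology))
        universe = list(protein.index)
        for name, reg in regulated.items():
            hits = [g for g in reg.index if g in set(universe)]
            if len(hits) < config.min_overlap:
                logger.info("%s: too few hits for enrichment", name)
                continue
            enr = fisher_enrichment(hits, universe, sets, config.min_overlap)
            if config.collapse_redundant_terms:
                enr = collapse_redundant(enr)
            enrichment[name] = enr
            enr.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)

    provenance = {
        "package": "plexcal",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "input_digests": {
            str(p): _sha256(p)
            for p in [*config.psm_paths, config.design_path]
            + ([config.impurity_path] if config.impurity_path else [])
        },
        "n_peptides_quantified": int(matrix.shape[0]),
        "n_peptides_after_filter": int(filtered.shape[0]),
        "n_proteins": int(protein.shape[0]),
        "n_samples": int(matrix.shape[1]),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return PipelineResult(
        peptide_matrix=matrix,
        peptide_annotations=annotations,
        protein_matrix=protein,
        removal_log=removal_log,
        qc_table=qc.table,
        pca_variance_explained=[float(v) for v in pc.variance_explained],
        de_results=de_results,
        regulated=regulated,
        enrichment=enrichment,
        provenance=provenance,
    )
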