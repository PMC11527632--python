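"""End-to-end derivation of the TLS signature score, configuration and
provenance, plus small quantification utilities (TMB from a MAF-like
table, specific lysis, tumor volume).

The derivation chain: preprocess -> consensus clusters on the signature
genes (TLS clusters) -> moderated-t DEGs -> consensus clusters on the DEGs
(gene clusters) -> moderated-t DEGs -> univariate Cox screen -> two-
component PCA score -> maximally selected cutpoint -> high/low survival
report. Rerunning with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusResult, consensus_cluster
from .diffexpr import moderated_t, write_deg_table
from .preprocess import (ClinicalTable, ExpressionMatrix, combat_correct,
                         fpkm_to_tpm, log_transform, tlsrg_genes, tlsrg_sets,
                         write_clinical, write_expression)
from .scoring import ScoreModel, dichotomize, fit_score_model, score_samples
from .survival import cox_univariate_screen, km_to_frame

KNOWN_NONSYNONYMOUS = {
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
}
KNOWN_SILENT = {
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA",
    "Splice_Region",
}


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the derivation, with the published
    defaults: DEG screens at BH-adjusted p < 0.01, univariate Cox keeps
    p < 0.05, consensus clustering over k = 2..9 with 1000 subsampling
    repetitions at fraction 0.8, PAC and cutpoint windows (0.1, 0.9)."""

    deg_adj_p: float = 0.01
    cox_p: float = 0.05
    k_min: int = 2
    k_max: int = 9
    n_reps: int = 1000
    subsample_frac: float = 0.8
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    maxstat_lower: float = 0.1
    maxstat_upper: float = 0.9
    ssgsea_alpha: float = 0.25
    inner_clusterer: str = "hierarchical"
    pseudocount: float = 1.0
    umi_max: int = 50_000
    umi_min: int = 1_000
    genes_max: int = 5_000
    genes_min: int = 300
    hgb_max: float = 0.05
    mito_max: float = 0.15
    exome_mb: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.deg_adj_p <= 1 and 0 < self.cox_p <= 1):
            raise ValueError("p thresholds must lie in (0, 1]")
        if not (0 <= self.pac_lower < self.pac_upper <= 1):
            raise ValueError("invalid PAC window")
        if not (0 <= self.maxstat_lower < self.maxstat_upper <= 1):
            raise ValueError("invalid maxstat window")
        if not (0 < self.subsample_frac <= 1):
            raise ValueError("subsample_frac must lie in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("invalid k range")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class DerivationArtifacts:
    """Everything the derivation produces, in execution order."""

    expression: ExpressionMatrix
    tls_clusters: ConsensusResult
    deg_tls: pd.DataFrame
    gene_clusters: ConsensusResult
    deg_gene: pd.DataFrame
    cox_screen: pd.DataFrame
    prognostic_genes: list[str]
    favorable_genes: list[str]
    model: ScoreModel
    score_table: pd.DataFrame
    survival_report: dict
    provenance: dict = field(default_factory=dict)


def _sha256_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def _two_largest(labels: pd.Series) -> pd.Series:
    """Restrict labels to the two largest clusters (binary DEG contrast)."""
    top = labels.value_counts().index[:2]
    return labels[labels.isin(top)]


def preprocess(expr: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    """Unit-normalize to log TPM and batch-correct when batches exist."""
    if expr.unit == "FPKM":
        expr = fpkm_to_tpm(expr)
    if expr.unit == "TPM":
        expr = log_transform(expr, pseudocount=config.pseudocount)
    if expr.unit != "logTPM":
        raise ValueError(f"cannot preprocess unit {expr.unit}")
    if expr.batch is not None and expr.batch.nunique() > 1:
        expr = combat_correct(expr)
    return expr


def run_derivation(expr: ExpressionMatrix, clinical: ClinicalTable,
                   config: PipelineConfig | None = None,
                   signature_genes: list[str] | None = None,
                   outdir=None) -> DerivationArtifacts:
    """Run the full signature derivation on one cohort.

    Parameters
    ----------
    signature_genes : list, optional
        The gene panel driving the first clustering; defaults to the
        packaged 23-gene TLS signature intersected with the matrix.
    outdir : path, optional
        When given, every stage writes a TSV plus a JSON provenance
        sidecar there; partial artifacts are retained if a stage fails.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "input_expression_sha256": _sha256_frame(expr.values),
        "input_clinical_sha256": _sha256_frame(clinical.table),
        "stages": [],
    }

    def checkpoint(stage: str, frame: pd.DataFrame | None = None) -> None:
        provenance["stages"].append(stage)
        if outdir is not None:
            if frame is not None:
                frame.to_csv(outdir / f"{stage}.tsv", sep="\t")
            with open(outdir / "provenance.json", "w") as fh:
                json.dump(provenance, fh, indent=1, default=str)

    stage = "preprocess"
    try:
        expr = preprocess(expr, config)
        common = [s for s in expr.sample_ids if s in clinical.table.index]
        if len(common) < expr.n_samples:
            warnings.warn(f"restricting to {len(common)} samples with clinical data")
            expr = ExpressionMatrix(expr.values[common], expr.unit,
                                    None if expr.batch is None else expr.batch[common])
        clinical = clinical.loc(expr.sample_ids)
        checkpoint(stage, expr.values)

        stage = "tls_clusters"
        if signature_genes is None:
            signature_genes = [g for g in tlsrg_genes() if g in expr.values.index]
        if len(signature_genes) < 2:
            raise ValueError("fewer than 2 signature genes present in the matrix")
        k_range = range(config.k_min, config.k_max + 1)
        tls_clusters = consensus_cluster(
            expr, features=signature_genes, k_range=k_range,
            n_reps=config.n_reps, subsample_frac=config.subsample_frac,
            seed=config.seed, inner=config.inner_clusterer)
        checkpoint(stage, tls_clusters.labels_series().to_frame())

        stage = "deg_tls"
        lab = _two_largest(tls_clusters.labels_series())
        sub = ExpressionMatrix(expr.values[lab.index], expr.unit)
        deg_tls = moderated_t(sub, lab, adj_threshold=config.deg_adj_p)
        degs1 = deg_tls.index[deg_tls["selected"]].tolist()
        if len(degs1) < 2:
            raise ValueError("fewer than 2 DEGs between TLS clusters")
        checkpoint(stage, deg_tls)

        stage = "gene_clusters"
        gene_clusters = consensus_cluster(
            expr, features=degs1, k_range=k_range,
            n_reps=config.n_reps, subsample_frac=config.subsample_frac,
            seed=config.seed + 1, inner=config.inner_clusterer)
        checkpoint(stage, gene_clusters.labels_series().to_frame())

        stage = "deg_gene"
        lab2 = _two_largest(gene_clusters.labels_series())
        sub2 = ExpressionMatrix(expr.values[lab2.index], expr.unit)
        deg_gene = moderated_t(sub2, lab2, adj_threshold=config.deg_adj_p)
        degs2 = deg_gene.index[deg_gene["selected"]].tolist()
        if len(degs2) < 3:
            raise ValueError("fewer than 3 DEGs between gene clusters")
        checkpoint(stage, deg_gene)

        stage = "cox_screen"
        cox = cox_univariate_screen(expr.subset_genes(degs2), clinical.time,
                                    clinical.event, p_threshold=config.cox_p)
        prognostic = cox.index[cox["selected"]].tolist()
        if len(prognostic) < 3:
            raise ValueError("fewer than 3 prognostic genes after the Cox screen")
        favorable = cox.index[cox["selected"] & (cox["hr"] < 1)].tolist()
        checkpoint(stage, cox)

        stage = "score"
        model = fit_score_model(expr, prognostic, favorable)
        scores = score_samples(model, expr)
        if outdir is not None:
            model.save(outdir / "score_model.json")
        checkpoint(stage, scores)

        stage = "dichotomize"
        score_table, report = dichotomize(
            scores, clinical,
            quantile_window=(config.maxstat_lower, config.maxstat_upper))
        checkpoint(stage, score_table)
        if outdir is not None:
            km_to_frame(report["km"]).to_csv(outdir / "km_curves.tsv",
                                             sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"derivation failed at stage {stage!r}: {err}") from err

    provenance["n_samples"] = expr.n_samples
    provenance["n_genes"] = expr.n_genes
    if outdir is not None:
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)

    return DerivationArtifacts(
        expression=expr, tls_clusters=tls_clusters, deg_tls=deg_tls,
        gene_clusters=gene_clusters, deg_gene=deg_gene, cox_screen=cox,
        prognostic_genes=prognostic, favorable_genes=favorable, model=model,
        score_table=score_table, survival_report=report, provenance=provenance)


# ---------------------------------------------------------------------------
# quantification utilities
# ---------------------------------------------------------------------------

def specific_lysis(test: float, spontaneous: float, maximal: float) -> float:
    """Percent specific lysis from an LDH-release cytotoxicity assay.

    [(test - spontaneous) / (maximal - spontaneous)] * 100.
    """
    if maximal <= spontaneous:
        raise ValueError("maximal release must exceed spontaneous release")
    return (test - spontaneous) / (maximal - spontaneous) * 100.0


def tumor_volume(length: float, width: float) -> float:
    """Tumor volume (mm^3) from caliper length and width: L * W^2 * 0.5."""
    if length < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    return length * width ** 2 * 0.5


def tmb_from_maf(mutations: pd.DataFrame, samples=None, exome_mb: float | None = 38.0,
                 nonsynonymous_only: bool = True,
                 count_unknown: bool = True) -> pd.Series:
    """Per-sample tumor mutational burden from a MAF-like table.

    Counts qualifying mutations per sample and divides by the captured
    exome size in megabases (``exome_mb=None`` returns raw counts). With
    ``nonsynonymous_only`` the silent/noncoding classes are excluded;
    unknown classification strings are counted or not per
    ``count_unknown`` (with a warning either way).

    ``samples`` supplies the full cohort so mutation-free samples get 0.
    """
    required = {"Tumor_Sample_Barcode", "Variant_Classification"}
    if not required <= set(mutations.columns):
        raise ValueError(f"mutation table must have columns {sorted(required)}")
    cls = mutations["Variant_Classification"]
    if nonsynonymous_only:
        known = cls.isin(KNOWN_NONSYNONYMOUS)
        silent = cls.isin(KNOWN_SILENT)
        unknown = ~known & ~silent
        if unknown.any():
            action = "counted" if count_unknown else "ignored"
            warnings.warn(f"{int(unknown.sum())} mutation(s) with unknown "
                          f"classification {action}: "
                          f"{sorted(cls[unknown].unique())[:5]}")
        keep = known | (unknown & count_unknown)
    else:
        keep = pd.Series(True, index=mutations.index)
    counts = mutations.loc[keep, "Tumor_Sample_Barcode"].value_counts()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    counts = counts.astype(float).rename("tmb")
    if exome_mb is not None:
        if exome_mb <= 0:
            raise ValueError("exome_mb must be positive")
        counts = counts / exome_mb
    return counts
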