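"""The TLS signature score: PCA over prognostic genes, per-sample score
PC1 - PC2, survival-guided dichotomization, and the score x TMB strata.

The score model is fit once (genes z-scored across the training samples,
SVD of the standardized matrix); new cohorts are scored with the stored
standardization and loadings, never re-fit. Because SVD signs are
arbitrary, PC1 is anchored so the mean loading over favorable-prognosis
(HR < 1) genes is positive — high score then tracks good prognosis — and
PC2's sign is fixed by making its largest-magnitude loading positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ClinicalTable, ExpressionMatrix
from .survival import (CutpointResult, kaplan_meier, logrank_test,
                       maxstat_cutpoint)

MODEL_FORMAT_VERSION = 1


@dataclass
class ScoreModel:
    """Fitted signature-score model (standardization + first two PCs)."""

    gene_ids: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    loadings1: np.ndarray
    loadings2: np.ndarray
    sign_anchor: list[str] = field(default_factory=list)
    explained_variance_ratio: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        for v in (self.loadings1, self.loadings2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("loadings must be unit norm")
        if abs(float(self.loadings1 @ self.loadings2)) > 1e-6:
            raise ValueError("loadings must be orthogonal")
        if (self.gene_sds <= 0).any():
            raise ValueError("gene sds must be positive")

    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "standardization": "population (n) denominator z-scores",
            "genes": [
                {"gene": g, "mean": float(m), "sd": float(s),
                 "loading1": float(l1), "loading2": float(l2)}
                for g, m, s, l1, l2 in zip(self.gene_ids, self.gene_means,
                                           self.gene_sds, self.loadings1,
                                           self.loadings2)],
            "sign_anchor": self.sign_anchor,
            "explained_variance_ratio": list(self.explained_variance_ratio),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["genes"]
        return cls(
            gene_ids=[r["gene"] for r in rows],
            gene_means=np.array([r["mean"] for r in rows]),
            gene_sds=np.array([r["sd"] for r in rows]),
            loadings1=np.array([r["loading1"] for r in rows]),
            loadings2=np.array([r["loading2"] for r in rows]),
            sign_anchor=payload.get("sign_anchor", []),
            explained_variance_ratio=tuple(payload.get("explained_variance_ratio",
                                                       (np.nan, np.nan))),
        )


def fit_score_model(m: ExpressionMatrix, prognostic_genes: Sequence[str],
                    favorable_genes: Sequence[str]) -> ScoreModel:
    """Fit the two-component signature model on a training cohort.

    Genes are z-scored across samples (population denominator); the SVD of
    the standardized genes x samples matrix yields unit gene-loading
    vectors for the two leading components. ``favorable_genes`` (the
    HR < 1 subset of the prognostic genes) orient PC1.
    """
    if m.unit != "logTPM":
        raise ValueError(f"expected logTPM input, got {m.unit}")
    genes = list(prognostic_genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 prognostic genes")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = m.subset_genes(genes)
    X = sub.values.to_numpy(dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=0)
    degenerate = sds <= 0
    if degenerate.any():
        dropped = [g for g, d in zip(genes, degenerate) if d]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        genes = [g for g, d in zip(genes, degenerate) if not d]
        if len(genes) < 3:
            raise ValueError("fewer than 3 non-degenerate genes")
        X, means, sds = X[~degenerate], means[~degenerate], sds[~degenerate]

    Z = (X - means[:, None]) / sds[:, None]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    if len(S) < 2 or S[1] <= 1e-10 * S[0]:
        raise ValueError("fewer than 2 non-degenerate principal components")
    u1, u2 = U[:, 0].copy(), U[:, 1].copy()

    anchor = [g for g in favorable_genes if g in genes]
    if anchor:
        anchor_idx = [genes.index(g) for g in anchor]
        if u1[anchor_idx].mean() < 0:
            u1 = -u1
    elif u1[np.argmax(np.abs(u1))] < 0:
        u1 = -u1
    if u2[np.argmax(np.abs(u2))] < 0:
        u2 = -u2

    total_var = float((S ** 2).sum())
    return ScoreModel(gene_ids=genes, gene_means=means, gene_sds=sds,
                      loadings1=u1, loadings2=u2, sign_anchor=anchor,
                      explained_variance_ratio=(float(S[0] ** 2 / total_var),
                                                float(S[1] ** 2 / total_var)))


def score_samples(model: ScoreModel, m: ExpressionMatrix,
                  allow_missing: bool = False) -> pd.DataFrame:
    """Score a cohort with a fitted model.

    Each sample's genes are standardized with the model's stored
    means/sds (no re-fitting) and projected on the two loading vectors;
    the signature score is pc1 - pc2. Missing model genes are an error
    unless ``allow_missing``, in which case they are mean-imputed (z = 0)
    with a warning.
    """
    if m.unit != "logTPM":
        raise ValueError(f"expected logTPM input, got {m.unit}")
    missing = [g for g in model.gene_ids if g not in m.values.index]
    if missing and not allow_missing:
        raise KeyError(f"model genes absent from cohort: {missing[:5]} "
                       "(pass allow_missing=True to mean-impute)")
    if missing:
        warnings.warn(f"mean-imputing {len(missing)} missing model gene(s)")

    Z = np.zeros((len(model.gene_ids), m.n_samples))
    for i, g in enumerate(model.gene_ids):
        if g in m.values.index:
            Z[i] = (m.values.loc[g].to_numpy(dtype=float) - model.gene_means[i]) \
                / model.gene_sds[i]
    pc1 = model.loadings1 @ Z
    pc2 = model.loadings2 @ Z
    return pd.DataFrame({"tlsscore": pc1 - pc2, "pc1": pc1, "pc2": pc2},
                        index=m.values.columns)


def dichotomize(scores: pd.DataFrame, clinical: ClinicalTable,
                quantile_window: tuple[float, float] = (0.1, 0.9)) -> tuple[pd.DataFrame, dict]:
    """Split samples at the maximally selected survival cutpoint.

    Returns the score table with ``group`` ('high' strictly above the
    cutpoint, else 'low') and ``cutpoint`` columns, plus a report with the
    cutpoint search, the high/low log-rank test and per-group KM curves.
    """
    common = [s for s in scores.index if s in clinical.table.index]
    if not common:
        raise ValueError("no overlapping samples between scores and clinical table")
    sc = scores.loc[common].copy()
    cl = clinical.loc(common)
    cut: CutpointResult = maxstat_cutpoint(sc["tlsscore"].to_numpy(),
                                           cl.time, cl.event,
                                           quantile_window=quantile_window)
    group = np.where(sc["tlsscore"] > cut.cutpoint, "high", "low")
    sc["group"] = group
    sc["cutpoint"] = cut.cutpoint
    chi2, df, p = logrank_test(cl.time, cl.event, group)
    km = {g: kaplan_meier(cl.time[group == g], cl.event[group == g])
          for g in ("high", "low")}
    report = {"cutpoint": cut, "logrank_chi2": chi2, "logrank_df": df,
              "logrank_p": p, "km": km,
              "n_high": int((group == "high").sum()),
              "n_low": int((group == "low").sum())}
    return sc, report


def score_tmb_strata(scores: pd.DataFrame, tmb: pd.Series, clinical: ClinicalTable,
                     tmb_cut: str = "median") -> tuple[pd.Series, dict]:
    """Cross the score groups with a TMB split into four survival strata.

    ``scores`` must already carry the high/low ``group`` column (see
    :func:`dichotomize`). TMB is split at its median (default) or at its
    own maximally selected cutpoint; empty strata are dropped with a
    warning and the log-rank df adjusted. The report also carries the
    Pearson and Spearman correlations between score and TMB.
    """
    common = [s for s in scores.index if s in tmb.index and s in clinical.table.index]
    if not common:
        raise ValueError("no overlapping samples")
    sc = scores.loc[common]
    if "group" not in sc.columns:
        raise ValueError("scores lack the high/low group column; run dichotomize first")
    t = tmb.loc[common].to_numpy(dtype=float)
    cl = clinical.loc(common)

    if tmb_cut == "median":
        cut_val = float(np.median(t))
        if np.ptp(t) == 0:
            raise ValueError("constant TMB; no cutpoint")
    elif tmb_cut == "maxstat":
        cut_val = maxstat_cutpoint(t, cl.time, cl.event).cutpoint
    else:
        raise ValueError(f"unknown tmb_cut {tmb_cut!r}")
    tmb_group = np.where(t > cut_val, "TMB-high", "TMB-low")

    labels = pd.Series([f"{s}-score/{tg}" for s, tg in zip(sc["group"], tmb_group)],
                       index=sc.index, name="stratum")
    sizes = labels.value_counts()
    keep = labels.isin(sizes[sizes > 0].index)
    if (~keep).any():
        warnings.warn("dropping empty stratum")
    chi2, df, p = logrank_test(cl.time[keep.to_numpy()], cl.event[keep.to_numpy()],
                               labels[keep].to_numpy())

    pear_r, pear_p = stats.pearsonr(sc["tlsscore"].to_numpy(), t)
    spear_r, spear_p = stats.spearmanr(sc["tlsscore"].to_numpy(), t)
    km = {g: kaplan_meier(cl.time[(labels == g).to_numpy()],
                          cl.event[(labels == g).to_numpy()])
          for g in labels.unique()}
    report = {"tmb_cutpoint": cut_val, "logrank_chi2": chi2, "logrank_df": df,
              "logrank_p": p, "pearson_r": float(pear_r), "pearson_p": float(pear_p),
              "spearman_r": float(spear_r), "spearman_p": float(spear_p),
              "km": km, "stratum_sizes": sizes.to_dict()}
    return labels, report
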