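"""Single-cell QC, normalization, HVG selection and binned-control module
scoring.

The module score is the per-cell mean expression of a gene module minus
the mean of expression-matched control genes: genes are binned by average
expression across cells and controls are drawn from the module genes'
bins, so depth- and expression-level effects cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .preprocess import GeneSet

QC_COLUMNS = ("total_umi", "n_genes_detected", "frac_mito", "frac_hemoglobin")

DEFAULT_MITO_PREFIXES = ("MT-",)
DEFAULT_HGB_PREFIXES = ("HBA", "HBB")


@dataclass
class CellMatrix:
    """Cells x genes count matrix with per-cell QC metrics.

    ``qc`` carries total_umi, n_genes_detected, frac_mito and
    frac_hemoglobin per cell; missing metrics are computed from the counts
    (fractions require mito/hemoglobin gene prefixes). ``cell_type`` and
    ``sample`` are optional per-cell labels.
    """

    counts: pd.DataFrame  # cells x genes, non-negative integers
    qc: pd.DataFrame | None = None
    cell_type: pd.Series | None = None
    sample: pd.Series | None = None
    mito_prefixes: tuple = DEFAULT_MITO_PREFIXES
    hgb_prefixes: tuple = DEFAULT_HGB_PREFIXES

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.qc is None or not set(QC_COLUMNS) <= set(self.qc.columns):
            self.qc = self._compute_qc(self.qc)
        self.qc = self.qc.loc[self.counts.index]
        for col in ("frac_mito", "frac_hemoglobin"):
            vals = self.qc[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        if self.cell_type is not None:
            self.cell_type = pd.Series(self.cell_type).reindex(self.counts.index)

    def _compute_qc(self, existing: pd.DataFrame | None) -> pd.DataFrame:
        counts = self.counts
        total = counts.sum(axis=1)
        detected = (counts > 0).sum(axis=1)
        mito = [g for g in counts.columns if str(g).startswith(self.mito_prefixes)]
        hgb = [g for g in counts.columns if str(g).startswith(self.hgb_prefixes)]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_mito = counts[mito].sum(axis=1) / total if mito else pd.Series(0.0, index=counts.index)
            frac_hgb = counts[hgb].sum(axis=1) / total if hgb else pd.Series(0.0, index=counts.index)
        qc = pd.DataFrame({"total_umi": total, "n_genes_detected": detected,
                           "frac_mito": frac_mito.fillna(0.0),
                           "frac_hemoglobin": frac_hgb.fillna(0.0)})
        if existing is not None:  # keep caller-supplied metrics where present
            for col in existing.columns:
                qc[col] = existing[col]
        return qc

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, cells) -> "CellMatrix":
        cells = list(cells)
        return CellMatrix(
            counts=self.counts.loc[cells].copy(),
            qc=self.qc.loc[cells].copy(),
            cell_type=None if self.cell_type is None else self.cell_type.loc[cells].copy(),
            sample=None if self.sample is None else self.sample.loc[cells].copy(),
            mito_prefixes=self.mito_prefixes, hgb_prefixes=self.hgb_prefixes)


# ---------------------------------------------------------------------------
# MTX / TSV IO
# ---------------------------------------------------------------------------

def write_mtx(cm: CellMatrix, prefix) -> None:
    """Matrix Market triplet (genes x cells) + genes/cells TSV sidecars."""
    mat = coo_matrix(cm.counts.to_numpy().T)
    mmwrite(f"{prefix}.mtx", mat)
    pd.Series(cm.gene_ids).to_csv(f"{prefix}.genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(f"{prefix}.cells.tsv", sep="\t", index=False, header=False)


def read_mtx(prefix) -> CellMatrix:
    mat = mmread(f"{prefix}.mtx").toarray().T  # cells x genes
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t", header=None)[0].tolist()
    return CellMatrix(counts=pd.DataFrame(mat, index=cells, columns=genes))


def read_dense_counts(path) -> CellMatrix:
    """Dense TSV fallback: cells in rows, genes in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellMatrix(counts=df)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(cm: CellMatrix, umi_max: int = 50_000, umi_min: int = 1_000,
              genes_max: int = 5_000, genes_min: int = 300,
              hgb_max: float = 0.05, mito_max: float = 0.15) -> CellMatrix:
    """Remove cells violating the QC thresholds.

    Removal is by strict inequality (UMI above ``umi_max`` or below
    ``umi_min``, detected genes above/below the gene bounds, hemoglobin
    fraction > ``hgb_max``, mitochondrial fraction > ``mito_max``); cells
    exactly at a bound are retained. Idempotent.
    """
    qc = cm.qc
    fail = {
        "umi_high": qc["total_umi"] > umi_max,
        "umi_low": qc["total_umi"] < umi_min,
        "genes_high": qc["n_genes_detected"] > genes_max,
        "genes_low": qc["n_genes_detected"] < genes_min,
        "hemoglobin": qc["frac_hemoglobin"] > hgb_max,
        "mito": qc["frac_mito"] > mito_max,
    }
    removed = pd.concat(fail, axis=1).any(axis=1)
    if removed.all():
        counts = {k: int(v.sum()) for k, v in fail.items()}
        raise ValueError(f"QC filter removed every cell; per-criterion counts: {counts}")
    return cm.subset_cells(qc.index[~removed])


# ---------------------------------------------------------------------------
# normalization / HVGs
# ---------------------------------------------------------------------------

def normalize_log1p(cm: CellMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """Depth-normalize and log transform: x -> ln(1 + scale * x / total)."""
    counts = cm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = [cm.cell_ids[i] for i in np.where(totals <= 0)[0][:5]]
        raise ValueError(f"zero-total cell(s) {bad}; run qc_filter first")
    out = np.log1p(scale * counts / totals[:, None])
    return pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)


def select_hvgs(normed: pd.DataFrame, n: int = 2000, window: int | None = None) -> list[str]:
    """Top-n highly variable genes by mean-trend-corrected log variance.

    The log variance is detrended against log mean with a running median
    (computed over genes ordered by mean); genes are ranked by the
    residual, ties broken by gene id.
    """
    n_genes = normed.shape[1]
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs from {n_genes} genes")
    mean = normed.mean(axis=0)
    var = normed.var(axis=0, ddof=1)
    eps = 1e-12
    logvar = np.log(var + eps)
    order = mean.sort_values(kind="stable").index
    if window is None:
        window = max(31, n_genes // 20) | 1
    trend = (pd.Series(logvar[order].to_numpy(), index=order)
             .rolling(window, center=True, min_periods=1).median())
    resid = pd.Series(logvar, index=normed.columns) - trend.reindex(normed.columns)
    ranking = sorted(normed.columns, key=lambda g: (-resid[g], str(g)))
    return list(ranking[:n])


# ---------------------------------------------------------------------------
# module scoring
# ---------------------------------------------------------------------------

@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per cell
    module: str
    n_bins: int
    n_ctrl: int
    seed: int
    genes_used: list[str] = field(default_factory=list)


def module_score(normed: pd.DataFrame, module, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> ModuleScoreResult:
    """Binned-control module score per cell.

    Genes are cut into ``n_bins`` equal-size bins of average expression;
    each module gene contributes ``n_ctrl`` control genes sampled from its
    bin (module genes excluded; with replacement when the bin is small).
    score(cell) = mean module expression - mean control expression.
    """
    if isinstance(module, GeneSet):
        name, genes = module.name, list(module.genes)
    else:
        name, genes = "module", list(module)
    present = [g for g in genes if g in normed.columns]
    dropped = sorted(set(genes) - set(present))
    if dropped:
        warnings.warn(f"{len(dropped)} module gene(s) absent from matrix: {dropped[:5]}")
    if not present:
        raise ValueError("no module genes present in the matrix")
    if normed.shape[1] < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} bins")

    rng = np.random.default_rng(seed)
    avg = normed.mean(axis=0)
    # equal-size bins over the expression ranking; ties broken by gene id so
    # the binning (and hence the scores) ignores input gene order
    rank_order = sorted(normed.columns, key=lambda g: (avg[g], str(g)))
    bin_of = pd.Series(np.floor(np.arange(len(rank_order)) * n_bins / len(rank_order)).astype(int),
                       index=rank_order)

    module_set = set(present)
    controls: list[str] = []
    for g in sorted(present):
        pool = sorted(bin_of.index[(bin_of == bin_of[g]) & (~bin_of.index.isin(module_set))])
        if len(pool) == 0:
            warnings.warn(f"no control genes available in the bin of {g!r}; skipped")
            continue
        replace = len(pool) < n_ctrl
        controls.extend(rng.choice(pool, size=n_ctrl, replace=replace))
    if not controls:
        raise ValueError("no control genes could be drawn")

    mod_mean = normed[present].mean(axis=1)
    ctrl_mean = normed[controls].to_numpy().mean(axis=1)
    scores = mod_mean - ctrl_mean
    return ModuleScoreResult(scores=scores.rename(name), module=name,
                             n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
                             genes_used=present)


def compare_scores_by_group(result: ModuleScoreResult, groups) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum comparison of module scores across groups.

    Returns one row per group pair with the rank-sum statistic, raw p and
    BH-adjusted p; per-group means/medians are in ``.attrs['summary']``.
    Singleton groups are skipped with a warning.
    """
    from .diffexpr import bh_adjust, compare_groups

    groups = pd.Series(list(groups), index=result.scores.index)
    levels = sorted(groups.unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    usable = []
    for lev in levels:
        if (groups == lev).sum() < 2:
            warnings.warn(f"singleton group {lev!r} skipped")
        else:
            usable.append(lev)

    rows = []
    for i, g1 in enumerate(usable):
        for g2 in usable[i + 1:]:
            mask = groups.isin([g1, g2])
            stat, p = compare_groups(result.scores[mask].to_numpy(),
                                     groups[mask].to_numpy(), test="wilcoxon")
            rows.append({"group1": g1, "group2": g2,
                         "n1": int((groups == g1).sum()), "n2": int((groups == g2).sum()),
                         "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    summary = result.scores.groupby(groups).agg(["mean", "median", "count"])
    out.attrs["summary"] = summary
    return out
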