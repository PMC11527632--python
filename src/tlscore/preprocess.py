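"""Expression-matrix containers, file IO and bulk preprocessing.

The bulk pipeline starts from FPKM (or microarray intensities treated as
such), converts to TPM, moves to log2 scale and, when several cohorts are
merged, removes batch location/scale effects with a parametric
empirical-Bayes adjustment (the classic ComBat recipe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("FPKM", "TPM", "logTPM", "counts")

_NA_VALUES = [".", "NA", "", "NaN", "nan"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples. Row/column labels must be
        unique, entries finite.
    unit : str
        One of ``FPKM``, ``TPM``, ``logTPM``, ``counts``. Unit transitions
        happen only through the declared operations (:func:`fpkm_to_tpm`,
        :func:`log_transform`).
    batch : pandas.Series, optional
        Per-sample batch label, indexed like ``values.columns``.
    """

    values: pd.DataFrame
    unit: str
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.unit in ("FPKM", "TPM") and (arr < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")
        if self.batch is not None:
            self.batch = pd.Series(self.batch).reindex(self.values.columns)
            if self.batch.isna().any():
                raise ValueError("batch labels missing for some samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.unit,
                                None if self.batch is None else self.batch.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.unit,
                                None if self.batch is None else self.batch.copy())


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``table`` is indexed by sample id and carries at least ``time``
    (non-negative, unit passed through untouched) and ``event`` (0/1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if (t["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("survival times must be non-negative")
        ev = t["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def loc(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(samples)].copy())


@dataclass
class GeneSet:
    """Named gene set; ``category`` holds the functional class annotation."""

    name: str
    genes: list[str]
    category: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "," if head.count(",") > head.count("\t") else "\t"


def read_expression(path, unit: str, clinical: ClinicalTable | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV/CSV.

    If the row labels look like the clinical table's sample ids (transposed
    file), the matrix is flipped with a warning.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, na_values=_NA_VALUES)
    df = df.dropna(how="all")
    if clinical is not None:
        samples = set(clinical.sample_ids)
        row_hits = np.mean([r in samples for r in df.index])
        col_hits = np.mean([c in samples for c in df.columns])
        if row_hits > col_hits and row_hits > 0.5:
            warnings.warn("expression file appears transposed (samples in rows); flipping")
            df = df.T
    if df.index.duplicated().any():
        df = collapse_duplicate_genes(df)
    return ExpressionMatrix(df.astype(float), unit)


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the max-variance row per duplicated gene symbol (logged)."""
    n_dup = int(df.index.duplicated().sum())
    warnings.warn(f"collapsing {n_dup} duplicated gene symbols (keeping max-variance row)")
    var = df.var(axis=1)
    order = np.argsort(-var.to_numpy(), kind="stable")
    kept = df.iloc[order]
    kept = kept[~kept.index.duplicated(keep="first")]
    return kept.loc[df.index.unique()]


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, na_values=_NA_VALUES)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path) -> None:
    c.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets.append(GeneSet(name=name, genes=genes, category=desc or None))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.category or ""] + list(s.genes)) + "\n")


def tlsrg_sets() -> dict[str, GeneSet]:
    """The packaged 23-gene tertiary-lymphoid-structure signature.

    Returns every packaged set keyed by name: the full 23-gene set
    (``TLSRG_ALL``), the functional category subsets, and the
    favorable/adverse prognosis splits used to orient the score.
    """
    ref = resources.files("tlscore.data").joinpath("tlsrg.gmt")
    with resources.as_file(ref) as path:
        sets = read_gmt(path)
    return {s.name: s for s in sets}


def tlsrg_genes() -> list[str]:
    """The 23 TLS-related gene symbols."""
    return list(tlsrg_sets()["TLSRG_ALL"].genes)


# ---------------------------------------------------------------------------
# unit transforms
# ---------------------------------------------------------------------------

def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM columns to transcripts-per-million.

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6, so every sample column sums to
    one million. Idempotent on already-TPM-scaled input.
    """
    if m.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {m.unit}")
    colsum = m.values.sum(axis=0)
    zero = colsum[colsum <= 0]
    if len(zero):
        raise ValueError(f"all-zero expression for sample(s): {list(zero.index)[:5]}")
    out = m.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(out, "TPM", None if m.batch is None else m.batch.copy())


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount)."""
    if m.unit != "TPM":
        raise ValueError(f"expected TPM input, got {m.unit}")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative values in TPM matrix")
    out = np.log2(m.values + pseudocount)
    return ExpressionMatrix(out, "logTPM", None if m.batch is None else m.batch.copy())


def inverse_log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Invert :func:`log_transform` (used to manufacture FPKM-like input)."""
    if m.unit != "logTPM":
        raise ValueError(f"expected logTPM input, got {m.unit}")
    out = np.exp2(m.values) - pseudocount
    out = out.clip(lower=0.0)
    return ExpressionMatrix(out, "TPM", None if m.batch is None else m.batch.copy())


# ---------------------------------------------------------------------------
# batch correction (parametric empirical Bayes, ComBat-style)
# ---------------------------------------------------------------------------

def _it_sol(s_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
            gamma_bar: float, t2: float, a_prior: float, b_prior: float,
            conv: float = 1e-4, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior-mode solution for per-gene batch effects.

    ``s_batch`` is the standardized data restricted to one batch
    (genes x n_b). gamma/delta estimates are shrunk toward the normal /
    inverse-gamma priors whose hyperparameters were fit by moments.
    """
    n_b = s_batch.shape[1]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    ssq_about = lambda g: ((s_batch - g[:, None]) ** 2).sum(axis=1)
    for _ in range(max_iter):
        gamma_new = (n_b * t2 * gamma_hat + delta_star * gamma_bar) / (n_b * t2 + delta_star)
        delta_new = (b_prior + 0.5 * ssq_about(gamma_new)) / (n_b / 2 + a_prior - 1)
        change = max(np.max(np.abs(gamma_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
                     np.max(np.abs(delta_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)))
        gamma_star, delta_star = gamma_new, delta_new
        if change < conv:
            break
    return gamma_star, delta_star


def combat_correct(m: ExpressionMatrix, batch: Sequence | None = None,
                   mean_only: bool = False) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Genes are standardized by the grand mean and pooled variance; per-batch
    gene effects (location gamma, scale delta^2) are estimated, shrunk
    toward moment-matched normal / inverse-gamma priors, removed, and the
    data back-transformed. With a single batch the input is returned
    unchanged. Genes with zero pooled variance cannot be standardized and
    are passed through with a warning.

    Parameters
    ----------
    batch : sequence, optional
        Per-sample batch labels; defaults to ``m.batch``.
    mean_only : bool
        Adjust locations only (delta* fixed at 1), for batches believed to
        share a common scale.
    """
    if m.unit != "logTPM":
        raise ValueError(f"batch correction expects logTPM input, got {m.unit}")
    if batch is None:
        if m.batch is None:
            raise ValueError("no batch labels supplied")
        batch = m.batch
    batch = pd.Series(list(batch), index=m.values.columns)
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        return ExpressionMatrix(m.values.copy(), m.unit, batch)

    counts = batch.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"batch(es) with a single sample: {list(singletons.index)}")

    X = m.values.to_numpy(dtype=float)
    n_genes, n = X.shape
    masks = {lev: (batch == lev).to_numpy() for lev in levels}
    n_b = {lev: int(masks[lev].sum()) for lev in levels}

    batch_means = np.column_stack([X[:, masks[lev]].mean(axis=1) for lev in levels])
    weights = np.array([n_b[lev] / n for lev in levels])
    grand_mean = batch_means @ weights
    lev_index = {lev: j for j, lev in enumerate(levels)}
    col_idx = np.array([lev_index[b] for b in batch])
    resid = X - batch_means[:, col_idx]
    var_pooled = (resid ** 2).mean(axis=1)

    degenerate = var_pooled <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance gene(s) passed through uncorrected")
    ok = ~degenerate

    Xc = X.copy()
    s = (X[ok] - grand_mean[ok, None]) / np.sqrt(var_pooled[ok, None])

    s_corr = np.empty_like(s)
    for lev in levels:
        mask = masks[lev]
        sb = s[:, mask]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        t2 = float(gamma_hat.var(ddof=1))
        d_mean = float(delta_hat.mean())
        d_var = float(delta_hat.var(ddof=1))
        if d_var <= 0:
            a_prior, b_prior = 2.0, d_mean
        else:
            a_prior = (2 * d_var + d_mean ** 2) / d_var
            b_prior = (d_mean * d_var + d_mean ** 3) / d_var
        if mean_only:
            gamma_star = (n_b[lev] * t2 * gamma_hat + 1.0 * gamma_bar) / (n_b[lev] * t2 + 1.0) \
                if t2 > 0 else gamma_hat
            delta_star = np.ones_like(delta_hat)
        elif t2 <= 0:
            gamma_star, delta_star = gamma_hat, delta_hat
        else:
            gamma_star, delta_star = _it_sol(sb, gamma_hat, delta_hat,
                                             gamma_bar, t2, a_prior, b_prior)
        s_corr[:, mask] = (sb - gamma_star[:, None]) / np.sqrt(delta_star[:, None])

    Xc[ok] = s_corr * np.sqrt(var_pooled[ok, None]) + grand_mean[ok, None]
    out = pd.DataFrame(Xc, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, "logTPM", batch)
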