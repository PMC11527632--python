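"""Rank-based single-sample enrichment (ssGSEA) and ESTIMATE-style
stromal/immune/purity scores.

For a sample, genes are ranked by expression and the enrichment score of a
gene set is the summed gap between a rank-weighted in-set cumulative
distribution and the unweighted out-of-set ECDF. Scores depend only on the
within-sample ranking, so any strictly increasing transform of a sample's
expression leaves its score unchanged.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix, GeneSet

# ESTIMATE purity calibration (fitted on TCGA Affymetrix data; applied to
# other platforms the constants are an approximation, not a re-fit)
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


def _sample_es(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score for one sample column.

    expr: per-gene expression; in_set: boolean membership mask.
    Genes are walked in descending expression order; the in-set running sum
    weights genes by rank^alpha (ranks from :func:`scipy.stats.rankdata`,
    high expression = high rank), the out-of-set running sum is the ECDF.
    """
    n = expr.size
    ranks = rankdata(expr)  # average ties; 1 = lowest expression
    order = np.argsort(-expr, kind="stable")
    in_ordered = in_set[order]
    w = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    denom_in = w.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(m, sets: Sequence[GeneSet], alpha: float = 0.25,
           normalize: bool = False) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores.

    Parameters
    ----------
    m : ExpressionMatrix or DataFrame
        Genes x samples.
    sets : sequence of GeneSet
        Sets sharing no genes with the matrix score NA (with a warning);
        a set covering every gene is an error (no out-of-set ECDF).
    alpha : float
        Rank-weighting exponent; 0 reduces the in-set term to an
        unweighted ECDF.
    normalize : bool
        Rescale the whole table by its global (max - min).

    Returns
    -------
    DataFrame samples x set names with ``alpha``/``normalized`` in .attrs.
    """
    values = m.values if isinstance(getattr(m, "values", None), pd.DataFrame) else pd.DataFrame(m)
    gene_index = {g: i for i, g in enumerate(values.index)}
    X = values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape

    out = np.full((n_samples, len(sets)), np.nan)
    for j, gs in enumerate(sets):
        idx = [gene_index[g] for g in gs.genes if g in gene_index]
        if not idx:
            warnings.warn(f"gene set {gs.name!r} shares no genes with the matrix; NA")
            continue
        if len(idx) >= n_genes:
            raise ValueError(f"gene set {gs.name!r} covers every gene")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        for s in range(n_samples):
            out[s, j] = _sample_es(X[:, s], mask, alpha)

    table = pd.DataFrame(out, index=values.columns, columns=[gs.name for gs in sets])
    if normalize:
        span = np.nanmax(out) - np.nanmin(out)
        if span > 0:
            table = table / span
    table.attrs.update({"alpha": alpha, "normalized": bool(normalize)})
    return table


def purity_from_estimate(estimate) -> np.ndarray:
    """Tumor purity from the combined estimate score.

    purity = cos(0.6049872018 + 0.0001467884 * estimate), clamped to [0, 1]
    with a warning outside the calibrated monotone domain.
    """
    estimate = np.asarray(estimate, dtype=float)
    arg = PURITY_INTERCEPT + PURITY_SLOPE * estimate
    purity = np.cos(arg)
    if ((arg < 0) | (arg > np.pi)).any():
        warnings.warn("estimate score outside the purity formula's monotone domain")
    clipped = np.clip(purity, 0.0, 1.0)
    if not np.allclose(clipped, purity):
        warnings.warn("purity clamped to [0, 1]")
    return clipped


def estimate_scores(m, stromal_set: GeneSet, immune_set: GeneSet) -> pd.DataFrame:
    """Stromal/immune enrichment, their sum, and the derived tumor purity."""
    es = ssgsea(m, [stromal_set, immune_set], alpha=0.25, normalize=False)
    stromal = es.iloc[:, 0]
    immune = es.iloc[:, 1]
    estimate = stromal + immune
    purity = purity_from_estimate(estimate.to_numpy())
    return pd.DataFrame({"stromal": stromal, "immune": immune,
                         "estimate": estimate,
                         "purity": pd.Series(purity, index=estimate.index)})


def synthetic_immune_sets(gene_ids: Sequence[str], n_sets: int = 6,
                          set_size: int = 30, seed: int = 0) -> list[GeneSet]:
    """Synthetic demo immune-signature collection (placeholder sets).

    Draws disjoint random gene sets from ``gene_ids`` for tests and demos;
    these are not curated biological signatures, and any user GMT can be
    supplied instead.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    if n_sets * set_size > len(gene_ids):
        raise ValueError("not enough genes for the requested collection")
    chosen = rng.choice(len(gene_ids), size=n_sets * set_size, replace=False)
    sets = []
    names = ["activated_B", "activated_CD4_T", "activated_CD8_T",
             "NK", "myeloid", "immature_B", "plasma", "mast", "Treg"]
    for i in range(n_sets):
        idx = chosen[i * set_size:(i + 1) * set_size]
        name = names[i] if i < len(names) else f"immune_set_{i + 1}"
        sets.append(GeneSet(name=name, genes=[gene_ids[j] for j in idx],
                            category="synthetic demo"))
    return sets
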