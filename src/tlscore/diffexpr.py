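"""Differential expression and generic group-comparison statistics.

The cluster-vs-cluster screens use an empirical-Bayes moderated t-statistic:
per-gene variances are shrunk toward a common prior fitted by moment
matching on the log residual variances, which stabilizes inference for
genes with few residual degrees of freedom. Genome-wide screens are
corrected with Benjamini-Hochberg; descriptive group comparisons use the
classical t / Wilcoxon / ANOVA tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import ExpressionMatrix


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p(i) = min over j with p(j) >= p(i) of min(1, p(j) * m / rank(j)).
    Monotone in p and invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Uses the distribution of log sample variances: with prior df d0 and
    residual df d, Var[log s^2] = trigamma(d/2) + trigamma(d0/2) and the
    mean identifies s0^2 through digamma offsets.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(m: ExpressionMatrix, groups, adj_threshold: float = 0.01,
                prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    Parameters
    ----------
    groups : sequence
        Per-sample binary labels; the two levels are ordered
        lexicographically and log_fc is level2 minus level1.
    adj_threshold : float
        BH-adjusted p cutoff for the ``selected`` flag.
    prior_df : float, optional
        Override the fitted prior degrees of freedom d0 (0 recovers the
        ordinary pooled-variance t exactly; inf fully shrinks).

    Returns
    -------
    pandas.DataFrame indexed by gene with columns log_fc, t_stat, p, adj_p,
    selected, zero_variance; the fitted (d0, s0_2) and group sizes are in
    ``.attrs``.
    """
    groups = pd.Series(list(groups), index=m.values.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    mask1 = (groups == levels[0]).to_numpy()
    mask2 = (groups == levels[1]).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (got {n1}, {n2})")

    X = m.values.to_numpy(dtype=float)
    m1 = X[:, mask1].mean(axis=1)
    m2 = X[:, mask2].mean(axis=1)
    ss1 = ((X[:, mask1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, mask2] - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (ss1 + ss2) / df_resid
    zero_var = s2 <= 0

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2 = fit_variance_prior(s2, df_resid)
    if d0 == 0:
        s2_tilde = s2.copy()
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
    else:
        s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)

    log_fc = m2 - m1
    denom = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(denom > 0, log_fc / denom, 0.0)
    df_total = d0 + df_resid
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    adj = bh_adjust(p)

    out = pd.DataFrame(
        {"log_fc": log_fc, "t_stat": t_stat, "p": p, "adj_p": adj,
         "selected": adj < adj_threshold, "zero_variance": zero_var},
        index=m.values.index,
    )
    out.attrs.update({"d0": d0, "s0_2": s0_2, "n1": n1, "n2": n2,
                      "group1": levels[0], "group2": levels[1],
                      "adj_threshold": adj_threshold})
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance gene(s); moderated "
                      "variance rescued by the prior")
    return out


def compare_groups(values, groups, test: str = "t") -> tuple[float, float]:
    """Classical comparison of a per-sample quantity across groups.

    ``test`` is one of ``t`` (two-sided Student), ``wilcoxon`` (rank-sum;
    exact for small tie-free samples, normal approximation with tie
    correction otherwise) or ``anova`` (one-way F). t and wilcoxon require
    exactly two groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if any((groups == lev).sum() == 0 for lev in levels):
        raise ValueError("empty group")
    samples = [values[groups == lev] for lev in levels]

    if test == "t":
        if len(levels) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # both groups constant and equal
            stat, p = 0.0, 1.0
        return stat, p
    if test == "wilcoxon":
        if len(levels) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        if np.ptp(values) == 0:
            warnings.warn("constant values under wilcoxon; p = 1")
            return 0.0, 1.0
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                 method="auto")
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.f_oneway(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):
            stat, p = 0.0, 1.0
        return stat, p
    raise ValueError(f"unknown test {test!r}")


def write_deg_table(deg: pd.DataFrame, path) -> None:
    """DEG table TSV with a comment header recording the screen settings."""
    a = deg.attrs
    with open(path, "w") as fh:
        fh.write(f"# moderated t: group1={a.get('group1')} (n={a.get('n1')}), "
                 f"group2={a.get('group2')} (n={a.get('n2')}); "
                 f"log_fc = group2 - group1\n")
        fh.write(f"# prior: d0={a.get('d0')}, s0_2={a.get('s0_2')}; "
                 f"adj_p threshold={a.get('adj_threshold')}\n")
        deg.to_csv(fh, sep="\t", index_label="gene_id")
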