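"""Survival machinery: Kaplan-Meier, log-rank, Cox regression and the
maximally selected log-rank cutpoint.

Everything here is written against the counting-process formulation:
subjects censored at an event time remain at risk through that time, ties
in the Cox partial likelihood are handled with Efron's correction, and the
cutpoint search standardizes the two-group log-rank statistic at every
candidate threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_ABS_BETA = 20.0  # cap under monotone likelihood (perfect separation)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t); S = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out


def _check_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty survival input")
    if (time < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    time, event = _check_surv(time, event)
    event_times = np.unique(time[event == 1])
    n_at_risk = np.array([(time >= t).sum() for t in event_times])
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(times=event_times, survival=surv,
                   at_risk=n_at_risk, events=d)


def km_to_frame(curves: dict[str, KMCurve]) -> pd.DataFrame:
    """Tidy (time, survival, group) table for export."""
    rows = []
    for g, c in curves.items():
        for t, s in zip(c.times, c.survival):
            rows.append({"time": t, "survival": s, "group": g})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(time, event, labels, levels):
    """Summed observed-minus-expected vector and covariance across event times."""
    k = len(levels)
    oe = np.zeros(k)
    V = np.zeros((k, k))
    event_times = np.unique(time[event == 1])
    group_idx = np.array([levels.index(g) for g in labels])
    for t in event_times:
        at_risk = time >= t
        n_j = int(at_risk.sum())
        d_j = int(((time == t) & (event == 1)).sum())
        if n_j <= 1:
            continue
        n_g = np.bincount(group_idx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(group_idx[(time == t) & (event == 1)], minlength=k).astype(float)
        frac = n_g / n_j
        oe += d_g - d_j * frac
        mult = d_j * (n_j - d_j) / (n_j - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    return oe, V


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """k-sample log-rank test.

    Returns (chi2, df, p) with the usual hypergeometric variance at each
    distinct event time and a chi-square reference on (k - 1) df.
    """
    time, event = _check_surv(time, event)
    labels = np.asarray(groups)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        if (labels == lev).sum() == 0:
            raise ValueError(f"empty group {lev!r}")
    oe, V = _logrank_oe(time, event, labels, levels)
    k = len(levels)
    sub = slice(0, k - 1)
    Vs = V[sub, sub]
    if np.allclose(Vs, 0):
        chi2 = 0.0
    else:
        chi2 = float(oe[sub] @ np.linalg.pinv(Vs) @ oe[sub])
        chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def logrank_z(time, event, in_group) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V).

    ``in_group`` is a boolean mask; the sign is positive when the masked
    group experiences more events than expected. Squares to the two-group
    log-rank chi-square.
    """
    time, event = _check_surv(time, event)
    mask = np.asarray(in_group, dtype=bool)
    labels = np.where(mask, "in", "out")
    oe, V = _logrank_oe(time, event, labels, ["in", "out"])
    if V[0, 0] <= 0:
        return 0.0
    return float(oe[0] / np.sqrt(V[0, 0]))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """One covariate row from a proportional-hazards fit."""

    name: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    n: int
    n_events: int
    se: float = field(default=np.nan)


def _cox_loglik(beta, X, time, event):
    """Efron partial log-likelihood, gradient and information matrix."""
    eta = X @ beta
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])

    ll = 0.0
    grad = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        S_r, S_d = w[risk].sum(), w[dead].sum()
        Sx_r, Sx_d = wx[risk].sum(axis=0), wx[dead].sum(axis=0)
        Sxx_r, Sxx_d = wxx[risk].sum(axis=0), wxx[dead].sum(axis=0)
        ll += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        for l in range(d):
            c = l / d
            denom = S_r - c * S_d
            num1 = Sx_r - c * Sx_d
            num2 = Sxx_r - c * Sxx_d
            ll -= np.log(denom)
            grad -= num1 / denom
            info += num2 / denom - np.outer(num1, num1) / denom ** 2
    return ll, grad, info


def cox_fit(time, event, covariates, names=None, tol: float = 1e-9,
            max_iter: int = 50) -> list[CoxResult]:
    """Newton-Raphson Cox fit on the Efron-tie partial likelihood.

    ``covariates`` is a DataFrame or 2-D array (samples x covariates);
    returns one :class:`CoxResult` per covariate from the joint fit. Wald
    standard errors come from the observed information. Monotone
    likelihoods (perfect separation) are flagged ``converged=False`` with
    |beta| capped.
    """
    time, event = _check_surv(time, event)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != time.size:
            X = X.T
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values")
    for j, nm in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate {nm!r}")

    center = X.mean(axis=0)
    Xc = X - center  # numerical conditioning; beta is unaffected

    beta = np.zeros(X.shape[1])
    ll_old, grad, info = _cox_loglik(beta, Xc, time, event)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, grad_new, info_new = _cox_loglik(beta_new, Xc, time, event)
            if ll_new >= ll_old - 1e-12:
                break
            factor /= 2.0
        beta, grad, info = beta_new, grad_new, info_new
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new

    capped = np.abs(beta) > MAX_ABS_BETA
    if capped.any():
        beta = np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA)
        converged = False
        warnings.warn("monotone partial likelihood; |beta| capped at "
                      f"{MAX_ABS_BETA} for {[names[j] for j in np.where(capped)[0]]}")

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)

    z975 = stats.norm.ppf(0.975)
    results = []
    for j, nm in enumerate(names):
        b, s = float(beta[j]), float(se[j])
        z = b / s if s > 0 else np.inf * np.sign(b)
        results.append(CoxResult(
            name=nm, beta=b, hr=float(np.exp(b)),
            ci_low=float(np.exp(b - z975 * s)), ci_high=float(np.exp(b + z975 * s)),
            p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
            converged=bool(converged and not capped[j]),
            n=int(time.size), n_events=int(event.sum()), se=s))
    return results


def cox_univariate_screen(m, time, event, p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene univariate Cox screen over an expression matrix.

    ``m`` is an :class:`~tlscore.preprocess.ExpressionMatrix` whose samples
    align with ``time``/``event``. Returns one row per gene with the Wald
    results and a ``selected`` flag at ``p < p_threshold``.
    """
    values = m.values if hasattr(m, "values") and isinstance(m.values, pd.DataFrame) else pd.DataFrame(m)
    rows = []
    for gene in values.index:
        x = values.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"gene_id": gene, "beta": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "converged": False, "selected": False})
            continue
        r = cox_fit(time, event, x[:, None], names=[gene])[0]
        rows.append({"gene_id": gene, "beta": r.beta, "hr": r.hr,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                     "converged": r.converged,
                     "selected": bool(r.p < p_threshold and r.converged)})
    out = pd.DataFrame(rows).set_index("gene_id")
    out.attrs["p_threshold"] = p_threshold
    return out


# ---------------------------------------------------------------------------
# maximally selected cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Best survival-separating threshold on a continuous score."""

    cutpoint: float
    max_statistic: float
    candidates_evaluated: int
    quantile_window: tuple[float, float]


def maxstat_cutpoint(score, time, event,
                     quantile_window: tuple[float, float] = (0.1, 0.9)) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Candidates are the distinct score values strictly inside the quantile
    window; each splits samples into (score <= c) vs (score > c) and is
    scored by the absolute standardized log-rank statistic. Ties are broken
    toward the candidate closest to the median score. The selected
    statistic is not corrected for the multiplicity of the search — the
    cutpoint only defines groups.
    """
    score = np.asarray(score, dtype=float)
    time, event = _check_surv(time, event)
    if score.size != time.size:
        raise ValueError("score/survival length mismatch")
    if score.size < 10:
        raise ValueError("need at least 10 samples for cutpoint search")
    lo, hi = np.quantile(score, quantile_window)
    candidates = np.unique(score)
    candidates = candidates[(candidates > lo) & (candidates < hi)]
    if candidates.size == 0:
        raise ValueError("no candidate cutpoints inside the quantile window")

    med = float(np.median(score))
    best = None  # (abs_z, -dist_to_median, candidate)
    n_eval = 0
    for c in candidates:
        high = score > c
        if event[high].sum() < 1 or event[~high].sum() < 1:
            continue
        z = logrank_z(time, event, high)
        n_eval += 1
        key = (abs(z), -abs(c - med), -c)
        if best is None or key > best[0]:
            best = (key, float(c), float(z))
    if best is None:
        raise ValueError("no valid candidate: events lie on one side of every cutpoint")
    return CutpointResult(cutpoint=best[1], max_statistic=abs(best[2]),
                          candidates_evaluated=n_eval,
                          quantile_window=tuple(quantile_window))


def cox_results_to_frame(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "covariate": r.name, "beta": r.beta, "hr": r.hr, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p, "converged": r.converged,
        "n": r.n, "n_events": r.n_events} for r in results]).set_index("covariate")
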