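"""Subsampled consensus clustering with PAC-based choice of k.

Samples are repeatedly subsampled, clustered at each candidate k, and the
co-assignment frequency of every sample pair (given co-sampling) is
accumulated into a consensus matrix. The proportion of ambiguous
clustering (PAC) — the fraction of pairs whose consensus lands in an
intermediate window — selects the cluster number: stable structure drives
pairwise consensus toward 0 or 1, minimizing PAC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # per-k symmetric samples x samples
    pac: dict[int, float]
    chosen_k: int
    labels: np.ndarray  # 1..chosen_k per sample
    n_reps: int
    subsample_frac: float
    sample_ids: list[str]

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def _correlation_distance(samples_by_features: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample rows; degenerate rows -> 1."""
    X = samples_by_features
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _cluster_subsample(X_sub: np.ndarray, k_list, method: str, rng) -> dict[int, np.ndarray]:
    """Cluster one subsample (samples x features) at every k."""
    if method == "hierarchical":
        from scipy.spatial.distance import pdist
        Z = linkage(pdist(X_sub), method="ward")
        return {k: fcluster(Z, t=k, criterion="maxclust") for k in k_list}
    if method == "correlation":
        dist = _correlation_distance(X_sub)
        Z = linkage(squareform(dist, checks=False), method="average")
        return {k: fcluster(Z, t=k, criterion="maxclust") for k in k_list}
    if method == "kmeans":
        from sklearn.cluster import KMeans
        out = {}
        for k in k_list:
            km = KMeans(n_clusters=k, n_init=3,
                        random_state=int(rng.integers(0, 2**31 - 1)))
            out[k] = km.fit_predict(X_sub) + 1
        return out
    raise ValueError(f"unknown inner clusterer {method!r}")


def consensus_cluster(m, features=None, k_range=range(2, 10), n_reps: int = 1000,
                      subsample_frac: float = 0.8, seed: int = 0,
                      inner: str = "hierarchical") -> ConsensusResult:
    """Consensus clustering over a feature (gene) submatrix.

    Parameters
    ----------
    m : ExpressionMatrix
        Genes x samples matrix; ``features`` selects the gene rows used
        for clustering (default: all).
    inner : {"hierarchical", "correlation", "kmeans"}
        Within-subsample clusterer. The default clusters gene-standardized
        samples with Euclidean/Ward hierarchical clustering, which detects
        mean-shift structure on a gene panel; ``correlation`` uses
        (1 - Pearson) distance with average linkage, which is blind to any
        shift component that is uniform across the panel genes.

    Notes
    -----
    consensus_ij = (# co-assigned) / (# co-sampled); pairs never co-sampled
    get 0 with a warning. Final labels cut an average-linkage tree over
    (1 - consensus) at the PAC-optimal k.
    """
    values = m.values if isinstance(getattr(m, "values", None), pd.DataFrame) else pd.DataFrame(m)
    if features is not None:
        missing = [f for f in features if f not in values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        values = values.loc[list(features)]
    G = values.to_numpy(dtype=float)  # genes x samples
    sd = G.std(axis=1)
    if (sd <= 0).all():
        raise ValueError("all features have zero variance")
    if (sd <= 0).any():
        warnings.warn(f"dropping {int((sd <= 0).sum())} zero-variance feature(s)")
        G, sd = G[sd > 0], sd[sd > 0]
    # standardize genes so distances weight the panel genes equally
    X = ((G - G.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x features
    n = X.shape[0]
    k_list = sorted(int(k) for k in k_range)
    if n < max(k_list) * 2:
        raise ValueError(f"need >= {max(k_list) * 2} samples for k up to {max(k_list)}")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_frac * n)), max(k_list))
    co_assigned = {k: np.zeros((n, n)) for k in k_list}
    co_sampled = np.zeros((n, n))

    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        labels_by_k = _cluster_subsample(X[idx], k_list, inner, rng)
        ix = np.ix_(idx, idx)
        co_sampled[ix] += 1.0
        for k in k_list:
            lab = labels_by_k[k]
            co_assigned[k][ix] += (lab[:, None] == lab[None, :])

    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(f"{int(never.sum() // 2)} sample pair(s) never co-sampled; "
                      "consensus set to 0")
    consensus = {}
    for k in k_list:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(co_sampled > 0, co_assigned[k] / np.maximum(co_sampled, 1), 0.0)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
        consensus[k] = C

    pac_by_k = {k: pac(consensus[k]) for k in k_list}
    chosen = choose_k(pac_by_k)

    # Ward on the consensus distance gives balanced final cuts; average
    # linkage tends to chain ambiguous samples into singletons here
    Zfin = linkage(squareform(np.clip(1.0 - consensus[chosen], 0, None), checks=False),
                   method="ward")
    labels = fcluster(Zfin, t=chosen, criterion="maxclust")

    return ConsensusResult(k_range=k_list, consensus=consensus, pac=pac_by_k,
                           chosen_k=chosen, labels=labels, n_reps=n_reps,
                           subsample_frac=subsample_frac,
                           sample_ids=list(values.columns))


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering.

    Fraction of strictly-upper-triangle consensus entries x with
    lower < x <= upper (the empirical CDF difference F(upper) - F(lower)).
    """
    if lower >= upper:
        raise ValueError("require lower < upper")
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    tri = C[np.triu_indices_from(C, k=1)]
    if tri.size == 0:
        return 0.0
    return float(np.mean((tri > lower) & (tri <= upper)))


def choose_k(pac_by_k: dict[int, float]) -> int:
    """k with minimal PAC; ties broken toward smaller k."""
    best_k, best_pac = None, np.inf
    for k in sorted(pac_by_k):
        if pac_by_k[k] < best_pac:
            best_k, best_pac = k, pac_by_k[k]
    return best_k


def consensus_to_frame(result: ConsensusResult, k: int | None = None) -> pd.DataFrame:
    k = result.chosen_k if k is None else k
    return pd.DataFrame(result.consensus[k], index=result.sample_ids,
                        columns=result.sample_ids)
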