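"""Endotype discovery: subsampled consensus k-medoids clustering.

PAM (partitioning around medoids) is implemented directly — greedy BUILD
initialization followed by best-improvement SWAP passes — because no
installed library provides k-medoids. Consensus clustering repeatedly
subsamples the cohort, clusters each subsample, and records how often each
sample pair lands in the same cluster when both are drawn. The number of
clusters is chosen by a committee of validity metrics (mean silhouette,
PAC, Calinski-Harabasz, Davies-Bouldin) aggregated by mean rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "manhattan_distances",
    "pam",
    "consensus_cluster",
    "select_k",
    "top_mad_genes",
    "ConsensusResult",
    "PamResult",
]


@dataclass
class PamResult:
    labels: np.ndarray  # cluster ids 1..k
    medoids: np.ndarray  # sample indices of the medoids
    cost: float


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    metrics: pd.DataFrame  # index k, columns mean_silhouette, PAC, calinski_harabasz, davies_bouldin
    k_selected: int
    final_labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    features: list[str] = field(default_factory=list)


def manhattan_distances(expr: pd.DataFrame, features=None) -> pd.DataFrame:
    """Pairwise Manhattan (city-block) distance between samples.

    ``expr`` is genes x samples; ``features`` optionally restricts to a gene
    subset.
    """
    if features is not None:
        features = list(features)
        if not features:
            raise ValueError("empty feature subset")
        expr = expr.loc[features]
    x = expr.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    d = cdist(x, x, metric="cityblock")
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def _check_dist(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return d


def pam(dist, k: int, seed: int | None = None) -> PamResult:
    """k-medoids by BUILD + best-improvement SWAP on a distance matrix.

    Deterministic: BUILD greedily adds the cost-minimizing medoid (ties to
    the lowest index); SWAP applies the single best improving
    medoid/non-medoid exchange until no exchange lowers the total cost.
    ``seed`` is accepted for interface uniformity but unused.
    """
    d = _check_dist(dist)
    n = d.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"require 2 <= k <= n, got k={k}, n={n}")
    if k == n:
        return PamResult(labels=np.arange(1, n + 1), medoids=np.arange(n), cost=0.0)

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        # adding candidate c changes cost by sum(min(nearest, d[c]) - nearest)
        gain = np.minimum(nearest[None, :], d).sum(axis=1)
        gain[medoids] = np.inf
        c = int(np.argmin(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, d[c])

    medoids = np.asarray(medoids)
    while True:
        dm = d[medoids]  # k x n
        order = np.argsort(dm, axis=0)
        near_i = order[0]  # index into medoids of nearest medoid per sample
        d1 = dm[near_i, np.arange(n)]
        d2 = dm[order[1], np.arange(n)]
        best_delta, best_swap = -1e-12, None
        for mi in range(len(medoids)):
            affected = near_i == mi
            # cost for sample j after removing medoid mi and adding candidate h:
            #   affected: min(d[h, j], d2[j]); else: min(d[h, j], d1[j])
            alt = np.where(affected, d2, d1)[None, :]
            new_cost = np.minimum(d, alt).sum(axis=1)
            delta = new_cost - d1.sum()
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    medoids = np.sort(medoids)
    dm = d[medoids]
    assign = np.argmin(dm, axis=0)
    cost = float(dm[assign, np.arange(n)].sum())
    return PamResult(labels=assign + 1, medoids=medoids, cost=cost)


def top_mad_genes(expr: pd.DataFrame, n_var_genes: int) -> list[str]:
    """Gene ids with the largest median absolute deviation across samples."""
    x = expr.to_numpy(dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    order = np.argsort(-mad, kind="stable")[: min(n_var_genes, len(mad))]
    return list(expr.index[np.sort(order)])


def consensus_cluster(
    expr: pd.DataFrame,
    k_range=range(2, 9),
    n_resamples: int = 250,
    subsample_fraction: float = 0.8,
    n_var_genes: int = 2000,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled consensus PAM over a range of cluster numbers.

    ``expr`` is normalized log2 expression (genes x samples). Features are
    the ``n_var_genes`` most variable genes by MAD. consensus(a, b) is the
    fraction of co-sampled resamples in which a and b co-clustered; final
    labels per k come from PAM on 1 - consensus.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    k_range = sorted(k_range)
    features = top_mad_genes(expr, n_var_genes)
    dist_df = manhattan_distances(expr, features)
    d = dist_df.to_numpy()
    n = d.shape[0]
    m = max(2, int(round(subsample_fraction * n)))

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    rows = []
    x_feat = expr.loc[features].to_numpy(dtype=float).T  # samples x features

    for k in k_range:
        hits = np.zeros((n, n))
        draws = np.zeros((n, n))
        # per-k substream so changing the k range never perturbs other draws
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = pam(d[np.ix_(idx, idx)], k)
            draws[np.ix_(idx, idx)] += 1
            for c in range(1, k + 1):
                members = idx[sub.labels == c]
                hits[np.ix_(members, members)] += 1
        off = ~np.eye(n, dtype=bool)
        if (draws[off] == 0).any():
            raise ValueError(
                "some sample pairs were never co-sampled; increase n_resamples "
                "or subsample_fraction"
            )
        cons = np.ones((n, n))
        cons[off] = hits[off] / draws[off]
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        lab = pam(1.0 - cons, k).labels
        labels[k] = lab
        upper = cons[np.triu_indices(n, k=1)]
        pac = float(np.mean((upper > 0.1) & (upper < 0.9)))
        rows.append(
            {
                "k": k,
                "mean_silhouette": float(silhouette_score(d, lab, metric="precomputed")),
                "PAC": pac,
                "calinski_harabasz": float(calinski_harabasz_score(x_feat, lab)),
                "davies_bouldin": float(davies_bouldin_score(x_feat, lab)),
            }
        )
    metrics = pd.DataFrame(rows).set_index("k")
    k_selected = k_range[0] if len(k_range) == 1 else select_k(metrics)
    return ConsensusResult(
        k_range=list(k_range),
        consensus=consensus,
        labels=labels,
        metrics=metrics,
        k_selected=k_selected,
        final_labels=labels[k_selected],
        sample_ids=list(expr.columns),
        features=features,
    )


def select_k(metrics: pd.DataFrame) -> int:
    """Committee vote over validity metrics by mean rank; ties to smaller k.

    Higher is better for mean silhouette and Calinski-Harabasz; lower is
    better for PAC and Davies-Bouldin.
    """
    required = {"mean_silhouette", "PAC", "calinski_harabasz", "davies_bouldin"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing {sorted(missing)}")
    if len(metrics) < 2 or metrics[sorted(required)].isna().any().any():
        raise ValueError("need >= 2 candidate k values with complete metrics")
    ranks = pd.DataFrame(
        {
            "mean_silhouette": metrics["mean_silhouette"].rank(ascending=False),
            "calinski_harabasz": metrics["calinski_harabasz"].rank(ascending=False),
            "PAC": metrics["PAC"].rank(ascending=True),
            "davies_bouldin": metrics["davies_bouldin"].rank(ascending=True),
        }
    )
    mean_rank = ranks.mean(axis=1)
    best = mean_rank[mean_rank == mean_rank.min()]
    return int(best.index.min())
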