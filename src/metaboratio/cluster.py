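"""Consensus correlation-distance K-means and cluster-number selection.

Cell lines are clustered with K-means under the "1 - Pearson correlation"
distance, realized exactly as Euclidean K-means on row-standardized data
(for rows standardized to mean 0 and unit sd, squared Euclidean distance
is monotone in 1 - r, and centroids remain well defined).  The procedure
is repeated many times from different initializations; the fraction of
repetitions in which two samples co-cluster forms a co-association matrix
whose average-linkage cut gives the consensus partition.

The number of clusters is chosen by majority vote of three heuristics:
the gap statistic, the elbow (distance-to-chord) rule on the
within-cluster dispersion curve, and the mean silhouette width.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ClusterResult, KDiagnostics, RatioMatrix


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, RatioMatrix):
        return X.values, X.sample_ids
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index)
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])]


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row to mean 0 and scale to sd 1 (population sd)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.zeros_like(X)
    np.divide(X - mu, sd, out=out, where=sd > 0)
    return out


def pearson_distance(X) -> np.ndarray:
    """Pairwise d(i, j) = 1 - Pearson r between sample rows; in [0, 2]."""
    Xv, ids = _as_matrix(X)
    if Xv.shape[1] < 2:
        raise ValueError("need at least 2 features per sample")
    sd = Xv.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance rows: {bad}")
    D = 1.0 - np.corrcoef(Xv)
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            idx = rng.choice(n, p=d2 / total)
        else:
            idx = rng.integers(n)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ centers.T
        + (centers**2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    respherize: bool = False,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd iterations with k-means++ init; optional centroid re-standardization.

    An emptied cluster is re-seeded at the point farthest from its
    assigned centroid.  Returns 0-based labels.
    """
    n = X.shape[0]
    centers = _kmeanspp_init(X, k, rng)
    if respherize:
        centers = standardize_rows(centers)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = _sq_distances(X, centers)
        new = d2.argmin(axis=1)
        for j in range(k):
            if not (new == j).any():
                far = d2[np.arange(n), new].argmax()
                new[far] = j
        if (new == labels).all():
            break
        labels = new
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
        if respherize:
            centers = standardize_rows(centers)
    return labels


def kmeans_correlation(X, k: int, seed: int = 0, max_iter: int = 300) -> np.ndarray:
    """Correlation-distance K-means; returns 0-based labels.

    Rows are standardized (mean 0, sd 1) so that squared Euclidean distance
    is monotone in 1 - Pearson r; centroids are re-standardized after each
    update so they stay on the same sphere as the data.
    """
    Xv, ids = _as_matrix(X)
    if k > Xv.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples ({Xv.shape[0]})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if Xv.shape[1] < 2:
        raise ValueError("need at least 2 features")
    sd = Xv.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance rows: {bad}")
    rng = np.random.default_rng(seed)
    return _lloyd(standardize_rows(Xv), k, rng, respherize=True, max_iter=max_iter)


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W.

    Defined as sum over clusters of (1 / 2 n_r) * sum of pairwise squared
    Euclidean distances, which for Euclidean geometry equals the
    within-cluster sum of squares about centroids.
    """
    X = np.asarray(X, dtype=float)
    W = 0.0
    for j in np.unique(labels):
        block = X[labels == j]
        W += ((block - block.mean(axis=0)) ** 2).sum()
    return float(W)


def consensus_cluster(
    X,
    k: int,
    n_reps: int = 1000,
    seed: int = 0,
    diagnostics: KDiagnostics | None = None,
) -> ClusterResult:
    """Repeat correlation K-means ``n_reps`` times and take the consensus.

    Repetition i runs with seed ``seed + i``.  The co-association matrix
    C(i, j) is the fraction of runs co-assigning i and j; the consensus
    labels are the average-linkage hierarchical cut of 1 - C into k groups.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    Xv, ids = _as_matrix(X)
    n = Xv.shape[0]
    C = np.zeros((n, n))
    for rep in range(n_reps):
        lab = kmeans_correlation(Xv, k, seed=seed + rep)
        C += lab[:, None] == lab[None, :]
    C /= n_reps
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    if k == 1 or n == 1:
        flat = np.ones(n, dtype=int)
    else:
        Z = linkage(squareform(1.0 - C, checks=False), method="average")
        flat = fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k' by first appearance so labels are surjective
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap) + 1) for c in flat])
    return ClusterResult(
        labels=pd.Series(labels, index=ids, name="cluster"),
        k=int(labels.max()),
        coassociation=pd.DataFrame(C, index=ids, columns=ids),
        n_reps=n_reps,
        seed=seed,
        diagnostics=diagnostics,
    )


def euclidean_kmeans(X, k: int, seed: int = 0, n_restarts: int = 2) -> np.ndarray:
    """Plain Euclidean K-means (best of ``n_restarts`` by dispersion), 0-based labels."""
    Xv, _ = _as_matrix(X)
    if k == 1:
        return np.zeros(Xv.shape[0], dtype=int)
    best, best_w = None, np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + 104729 * r)
        lab = _lloyd(Xv, k, rng)
        w = within_dispersion(Xv, lab)
        if w < best_w:
            best, best_w = lab, w
    return best


@dataclass
class GapResult:
    """Gap statistic curve: Gap(k), simulation se s_k, observed log W_k, chosen k."""

    gap: dict[int, float]
    se: dict[int, float]
    log_w: dict[int, float]
    chosen_k: int


def gap_statistic(
    X,
    k_range: Sequence[int],
    B: int = 50,
    seed: int = 0,
    cluster_fn: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
) -> GapResult:
    """Tibshirani-style gap statistic with a uniform-box reference.

    Gap(k) = mean_B[log W_k(reference)] - log W_k(data); references are
    drawn uniformly over each feature's observed range.  The chosen k is
    the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}; if no k qualifies,
    the argmax of Gap.  ``cluster_fn(X, k, seed) -> labels`` defaults to
    plain Euclidean K-means on the matrix exactly as given.
    """
    Xv, _ = _as_matrix(X)
    if Xv.shape[0] < 2:
        raise ValueError("gap statistic needs at least 2 samples")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if B < 2:
        raise ValueError("B must be >= 2")
    if cluster_fn is None:
        cluster_fn = euclidean_kmeans
    rng = np.random.default_rng(seed)
    lo, hi = Xv.min(axis=0), Xv.max(axis=0)
    refs = [lo + (hi - lo) * rng.random(Xv.shape) for _ in range(B)]
    gap, se, log_w = {}, {}, {}
    for k in ks:
        lw = np.log(max(within_dispersion(Xv, cluster_fn(Xv, k, seed)), 1e-300))
        lw_ref = np.array(
            [
                np.log(max(within_dispersion(R, cluster_fn(R, k, seed + 1 + b)), 1e-300))
                for b, R in enumerate(refs)
            ]
        )
        log_w[k] = float(lw)
        gap[k] = float(lw_ref.mean() - lw)
        se[k] = float(lw_ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / B))
    chosen = None
    for a, b in zip(ks[:-1], ks[1:]):
        if gap[a] >= gap[b] - se[b]:
            chosen = a
            break
    if chosen is None:
        chosen = max(gap, key=lambda k: (gap[k], -k))
    return GapResult(gap=gap, se=se, log_w=log_w, chosen_k=int(chosen))


def elbow_k(wss: dict[int, float] | Sequence[float], k_range: Sequence[int] | None = None) -> int:
    """Elbow pick: k maximizing perpendicular distance to the endpoint chord.

    Ties (e.g. a perfectly linear decline) break to the smallest k.
    """
    if isinstance(wss, dict):
        ks = sorted(wss)
        ws = np.array([wss[k] for k in ks], dtype=float)
    else:
        if k_range is None:
            raise ValueError("k_range required when wss is a sequence")
        ks = list(k_range)
        ws = np.asarray(wss, dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow needs at least 3 points on the curve")
    p1 = np.array([ks[0], ws[0]])
    p2 = np.array([ks[-1], ws[-1]])
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    pts = np.column_stack([ks, ws]) - p1
    dist = np.abs(chord[0] * pts[:, 1] - chord[1] * pts[:, 0]) / norm
    return int(ks[int(np.argmax(dist))])


def silhouette_widths(
    data, labels, metric: str = "euclidean"
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) and their mean.

    s(i) = (b - a) / max(a, b) with a the mean intra-cluster distance
    (excluding self) and b the smallest mean distance to another cluster.
    Members of singleton clusters get s = 0, as do samples with a = b = 0.
    ``metric`` is "euclidean", "pearson", or "precomputed" (``data`` is
    then the distance matrix itself).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if metric == "precomputed":
        D = np.asarray(data, dtype=float)
    elif metric == "pearson":
        D = pearson_distance(data)
    elif metric == "euclidean":
        Xv, _ = _as_matrix(data)
        D = np.sqrt(_sq_distances(Xv, Xv))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = D.shape[0]
    sums = np.column_stack([D[:, labels == c].sum(axis=1) for c in uniq])
    counts = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if counts[c] == 1:
            continue
        a = sums[i, c] / (counts[c] - 1)
        other = [sums[i, j] / counts[j] for j in range(len(uniq)) if j != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def select_k(gap_k: int, elbow_choice: int, silhouette_k: int) -> int:
    """Majority vote among the three heuristics; a three-way tie defers to silhouette."""
    votes = Counter([gap_k, elbow_choice, silhouette_k])
    top, n = votes.most_common(1)[0]
    return int(top) if n >= 2 else int(silhouette_k)


def k_diagnostics(
    X,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
    n_restarts: int = 5,
    gap_B: int = 50,
) -> KDiagnostics:
    """Run all three heuristics over ``k_range`` and combine them.

    The dispersion curve (for the elbow) and the gap statistic additionally
    probe k = 1.  WSS per k is the best of ``n_restarts`` correlation
    K-means runs; silhouettes use the same best labels under the Pearson
    distance; the gap statistic runs on the row-standardized matrix, where
    Euclidean K-means coincides with correlation K-means.
    """
    Xv, _ = _as_matrix(X)
    ks_sel = sorted(set(int(k) for k in k_range))
    if not ks_sel:
        raise ValueError("empty k_range")
    ks_curve = sorted(set([1] + ks_sel))
    Xs = standardize_rows(Xv)
    D = pearson_distance(Xv)

    wss: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in ks_curve:
        best, best_w = None, np.inf
        for r in range(n_restarts):
            lab = kmeans_correlation(Xv, k, seed=seed + 7919 * r)
            w = within_dispersion(Xs, lab)
            if w < best_w:
                best, best_w = lab, w
        wss[k] = best_w
        best_labels[k] = best

    sil = {
        k: silhouette_widths(D, best_labels[k], metric="precomputed")[1]
        for k in ks_sel
        if k >= 2 and len(np.unique(best_labels[k])) >= 2
    }
    sil_k = max(sil, key=lambda k: (sil[k], -k))
    gap = gap_statistic(Xs, ks_curve, B=gap_B, seed=seed)
    elbow_choice = elbow_k(wss)
    combined = select_k(gap.chosen_k, elbow_choice, sil_k)
    return KDiagnostics(
        k_range=ks_curve,
        wss=wss,
        gap=gap.gap,
        gap_se=gap.se,
        silhouette=sil,
        gap_k=gap.chosen_k,
        elbow_k=elbow_choice,
        silhouette_k=int(sil_k),
        combined_k=int(combined),
    )
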