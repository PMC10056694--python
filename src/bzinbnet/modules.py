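"""Module (cluster) identification from correlation affinities.

Correlation matrices are turned into non-negative, zero-diagonal
affinities (negative correlations are clamped to zero: only positive
inter-dependencies define modules), clustered with a symmetric
normalized-Laplacian spectral embedding plus seeded k-means, and
evaluated against ground truth with a mode-matching accuracy procedure
and the Adjusted Rand Index.  Frobenius distances between correlation
(sub-)matrices quantify network differences between conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .correlation import CorrMatrix

__all__ = [
    "AffinityMatrix",
    "ClusterSolution",
    "MatchResult",
    "to_affinity",
    "SpectralModules",
    "spectral_cluster",
    "eigengap_k",
    "match_clusters",
    "adjusted_rand_index",
    "submatrix_distance",
    "nested_distance_curve",
    "standardize_counts",
]


@dataclass
class AffinityMatrix:
    """Square non-negative similarity matrix with zero diagonal."""

    values: np.ndarray
    ids: pd.Index
    method: str = "unknown"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be square")
        self.values = v


@dataclass
class ClusterSolution:
    """Per-feature labels in {1..k} plus eigenvalue diagnostics."""

    labels: np.ndarray
    k: int
    seed: int
    eigenvalues: np.ndarray
    ids: Optional[pd.Index] = None
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class MatchResult:
    """Bijective matching of predicted clusters onto truth clusters."""

    mapping: Dict[int, int]  # predicted cluster -> truth cluster
    accuracy: float
    per_cluster: Dict[int, float]  # truth cluster -> proportion recovered


def _corr_values(corr) -> Tuple[np.ndarray, pd.Index]:
    if isinstance(corr, CorrMatrix):
        if not corr.square:
            raise ValueError("affinity construction needs a square matrix")
        return corr.values.to_numpy(dtype=float), corr.values.index
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy(dtype=float), corr.index
    arr = np.asarray(corr, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def to_affinity(corr) -> AffinityMatrix:
    """Correlations -> affinities: clamp negatives to zero, zero the
    diagonal, replace missing entries by zero (with a warning) and
    symmetrize by averaging."""
    vals, ids = _corr_values(corr)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("affinity construction needs a square matrix")
    a = vals.copy()
    n_missing = int(np.isnan(a).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing correlation entries set to zero affinity",
            stacklevel=2,
        )
        a = np.nan_to_num(a, nan=0.0)
    a = (a + a.T) / 2.0
    np.clip(a, 0.0, None, out=a)
    np.fill_diagonal(a, 0.0)
    method = corr.method if isinstance(corr, CorrMatrix) else "unknown"
    return AffinityMatrix(a, ids, method)


def _normalized_laplacian_eigs(a: np.ndarray, n_vec: int):
    """Smallest symmetric-normalized-Laplacian eigenpairs.

    Returns (eigenvalues ascending, embedding columns) computed on the
    non-isolated nodes; isolated (zero-degree) rows are excluded.
    """
    d = a.sum(axis=1)
    keep = d > 0
    sub = a[np.ix_(keep, keep)]
    dk = d[keep]
    inv_sqrt = 1.0 / np.sqrt(dk)
    m = sub * inv_sqrt[:, None] * inv_sqrt[None, :]
    w, v = eigh(m)
    # eigenvalues of L_sym = 1 - eigenvalues of the normalized affinity
    lam = 1.0 - w[::-1]
    vec = v[:, ::-1]
    return lam, vec[:, :n_vec], keep


class SpectralModules(BaseEstimator, ClusterMixin):
    """Spectral clustering of a correlation affinity into k modules.

    The symmetric normalized Laplacian embedding (k leading
    eigenvectors, rows unit-normalized) is clustered with seeded
    k-means.  Zero-degree nodes cannot be embedded; they are assigned to
    the cluster with the nearest centroid in the raw affinity row space
    and reported in ``isolated_``.

    Attributes
    ----------
    labels_ : ndarray of int, cluster labels in {1..k}
    eigenvalues_ : ndarray, ascending Laplacian spectrum (diagnostics)
    isolated_ : ndarray of int, indices of zero-degree nodes
    """

    def __init__(self, n_clusters: int = 10, n_init: int = 20, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        a = X.values if isinstance(X, AffinityMatrix) else np.asarray(X, dtype=float)
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if a.shape[0] < k:
            raise ValueError("need at least n_clusters features")
        lam, emb, keep = _normalized_laplacian_eigs(a, k)
        norms = np.linalg.norm(emb, axis=1)
        emb = emb / np.where(norms > 0, norms, 1.0)[:, None]
        km = KMeans(
            n_clusters=k, n_init=self.n_init, random_state=self.random_state
        ).fit(emb)
        labels = np.zeros(a.shape[0], dtype=np.int64)
        labels[keep] = km.labels_ + 1
        isolated = np.flatnonzero(~keep)
        if isolated.size:
            # nearest cluster centroid in raw affinity row space
            centroids = np.stack(
                [a[keep][km.labels_ == c].mean(axis=0) for c in range(k)]
            )
            for i in isolated:
                labels[i] = int(np.argmin(np.linalg.norm(centroids - a[i], axis=1))) + 1
        self.labels_ = labels
        self.eigenvalues_ = lam
        self.isolated_ = isolated
        return self


def spectral_cluster(aff, k: int, seed: int = 0, n_init: int = 20) -> ClusterSolution:
    """Functional wrapper over :class:`SpectralModules`."""
    est = SpectralModules(n_clusters=k, n_init=n_init, random_state=seed).fit(aff)
    ids = aff.ids if isinstance(aff, AffinityMatrix) else None
    return ClusterSolution(
        est.labels_, k, seed, est.eigenvalues_, ids, est.isolated_
    )


def eigengap_k(aff, kmax: int) -> int:
    """Advisory cluster count: the k in 1..kmax maximizing the gap
    between consecutive ascending Laplacian eigenvalues (ties broken
    toward smaller k)."""
    a = aff.values if isinstance(aff, AffinityMatrix) else np.asarray(aff, dtype=float)
    if kmax >= a.shape[0]:
        raise ValueError("kmax must be below the feature count")
    lam, _, _ = _normalized_laplacian_eigs(a, a.shape[0])
    gaps = np.diff(lam[: kmax + 1])
    return int(np.argmax(gaps)) + 1


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    la, ia = np.unique(a, return_inverse=True)
    lb, ib = np.unique(b, return_inverse=True)
    table = np.zeros((la.size, lb.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement of two partitions (permutation model)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    t = _contingency(a, b)
    n = a.size

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(t).sum()
    sum_rows = comb2(t.sum(axis=1)).sum()
    sum_cols = comb2(t.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def match_clusters(pred, truth, k: int, exhaustive_limit: int = 10) -> MatchResult:
    """Match predicted clusters to truth clusters and score accuracy.

    Step 1 fixes every mutual-mode pair: truth cluster t and predicted
    cluster p are matched when p is the most common prediction within t
    and t is the most common truth within p (mode ties broken toward the
    lower cluster index).  The remaining clusters are matched by the
    bijection maximizing the overall proportion of correctly assigned
    features -- exhaustively up to ``exhaustive_limit`` remaining
    clusters, by optimal linear assignment (same objective) beyond that.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must cover the same features")
    labels = np.arange(1, k + 1)
    c = np.zeros((k, k), dtype=np.int64)  # c[t-1, p-1]
    for t, p in zip(truth, pred):
        if not (1 <= t <= k and 1 <= p <= k):
            raise ValueError("labels must lie in 1..k")
        c[t - 1, p - 1] += 1

    mode_pred = c.argmax(axis=1)  # per truth cluster (first index on ties)
    mode_truth = c.argmax(axis=0)  # per predicted cluster
    mapping: Dict[int, int] = {}
    for t in range(k):
        p = mode_pred[t]
        if mode_truth[p] == t:
            mapping[int(labels[p])] = int(labels[t])
    fixed_t = {v - 1 for v in mapping.values()}
    fixed_p = {p - 1 for p in mapping}
    rest_t = [t for t in range(k) if t not in fixed_t]
    rest_p = [p for p in range(k) if p not in fixed_p]
    if rest_t:
        sub = c[np.ix_(rest_t, rest_p)]
        if len(rest_t) <= exhaustive_limit:
            best, best_score = None, -1
            for perm in permutations(range(len(rest_p))):
                score = sum(sub[i, perm[i]] for i in range(len(rest_t)))
                if score > best_score:
                    best, best_score = perm, score
            assign = best
        else:
            _, assign = linear_sum_assignment(-sub)
        for i, j in enumerate(assign):
            mapping[int(labels[rest_p[j]])] = int(labels[rest_t[i]])
    correct = sum(c[t_lab - 1, p_lab - 1] for p_lab, t_lab in mapping.items())
    per_cluster = {
        t_lab: float(c[t_lab - 1, p_lab - 1] / max(c[t_lab - 1].sum(), 1))
        for p_lab, t_lab in mapping.items()
    }
    return MatchResult(mapping, float(correct / pred.size), per_cluster)


def submatrix_distance(corrA, corrB, features: Optional[Sequence] = None) -> float:
    """Frobenius norm of the difference between two correlation matrices
    restricted to a feature subset."""
    va, ia = _corr_values(corrA)
    vb, ib = _corr_values(corrB)
    da = pd.DataFrame(va, index=ia, columns=ia)
    db = pd.DataFrame(vb, index=ib, columns=ib)
    if features is None:
        features = da.index
    features = pd.Index(features)
    for d in (da, db):
        missing = features.difference(d.index)
        if len(missing):
            raise KeyError(f"unknown features: {list(missing)[:5]}")
    diff = da.loc[features, features].to_numpy() - db.loc[features, features].to_numpy()
    return float(np.linalg.norm(diff))


def nested_distance_curve(
    corrA, corrB, clusters: ClusterSolution
) -> List[Tuple[int, float]]:
    """Distances over nested cluster sets, largest-distance cluster first.

    Per-cluster Frobenius distances are computed, clusters sorted by
    decreasing distance, and the distance of the cumulative feature
    union reported for each nested set.
    """
    va, ia = _corr_values(corrA)
    ids = clusters.ids if clusters.ids is not None else ia
    ids = pd.Index(ids)
    per = []
    for lab in sorted(set(clusters.labels)):
        feats = ids[clusters.labels == lab]
        per.append((lab, submatrix_distance(corrA, corrB, feats)))
    per.sort(key=lambda t: -t[1])
    curve = []
    acc: List = []
    for lab, _ in per:
        acc.extend(ids[clusters.labels == lab])
        curve.append((len(acc), submatrix_distance(corrA, corrB, acc)))
    return curve


def standardize_counts(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Feature-wise standardization for heatmap display.

    Outliers beyond 3 x IQR from the first/third quartile are clipped to
    the fence, then each feature is centered at its median and divided
    by its standard deviation.  Zero-variance features come back as
    all-zero rows, flagged in the returned mask.
    """
    x = matrix.to_numpy(dtype=float)
    q1 = np.percentile(x, 25, axis=1, keepdims=True)
    q3 = np.percentile(x, 75, axis=1, keepdims=True)
    iqr = q3 - q1
    x = np.clip(x, q1 - 3 * iqr, q3 + 3 * iqr)
    med = np.median(x, axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    out = (x - med) / sd
    out[flat] = 0.0
    return (
        pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        pd.Series(flat, index=matrix.index, name="zero_variance"),
    )
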