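"""Temporal trajectory construction and DTW clustering of gene trajectories.

Time-course expression is averaged per timepoint, smoothed with a cubic
spline (5 df) and z-standardized per gene so that genes with similar
proportional dynamics are comparable. Genes with no significant age
association (no age coefficient at q < 0.01) form "cluster 0"; the rest are
clustered by complete-linkage agglomeration on pairwise dynamic-time-warping
distances (Sakoe-Chiba band of one timepoint, squared local cost) with DTW
barycenter averaging (DBA) for centroids. Cluster labels 1-5 are assigned by
centroid shape: monotone up, monotone down, early peak, late peak, mid
trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from ._utils import fit_spline
from .cohort import archetype_profile


@dataclass
class TrajectoryMatrix:
    """Gene x timepoint trajectory values on a shared age grid."""

    values: pd.DataFrame          # genes x timepoints
    ages: np.ndarray              # days, ascending
    standardized: bool = False
    constant: pd.Series | None = None  # genes flattened to zero by z-scoring


@dataclass
class ClusterAssignment:
    labels: pd.Series             # gene -> 0..k
    centroids: dict               # label (1..k) -> centroid series
    linkage: np.ndarray | None = None
    ages: np.ndarray | None = None


def average_by_timepoint(X: pd.DataFrame, meta: pd.DataFrame) -> TrajectoryMatrix:
    """Mean expression across time-course replicates at each age, per gene."""
    meta = meta.set_index("sample_id")
    tc = meta.loc[meta["group"] == "timecourse"]
    if tc.empty:
        raise ValueError("no time-course samples in metadata")
    ages = np.sort(tc["age_days"].unique())
    if len(ages) < 2:
        raise ValueError("need at least two timepoints")
    cols = {}
    for a in ages:
        sids = tc.index[tc["age_days"] == a]
        sids = [s for s in sids if s in X.columns]
        if not sids:
            raise ValueError(f"timepoint day {a} has no samples in the matrix")
        cols[a] = X[sids].mean(axis=1)
    values = pd.DataFrame(cols)
    return TrajectoryMatrix(values=values, ages=ages.astype(float))


def smooth_standardize(T: TrajectoryMatrix, df: int = 5) -> TrajectoryMatrix:
    """Smooth each trajectory with an exact-df cubic spline, then z-score.

    Constant trajectories (zero variance after smoothing) map to all-zeros
    and are flagged rather than producing NaNs.
    """
    if len(T.ages) < df + 1:
        raise ValueError(f"need at least {df + 1} timepoints for a {df}-df spline")
    Y = T.values.to_numpy()
    smooth = fit_spline(T.ages, Y, df=df)(T.ages)
    mean = smooth.mean(axis=1, keepdims=True)
    sd = smooth.std(axis=1, keepdims=True)
    constant = sd[:, 0] < 1e-12
    sd[constant] = 1.0
    z = (smooth - mean) / sd
    z[constant] = 0.0
    return TrajectoryMatrix(
        values=pd.DataFrame(z, index=T.values.index, columns=T.values.columns),
        ages=T.ages, standardized=True,
        constant=pd.Series(constant, index=T.values.index),
    )


# --------------------------------------------------------------------- DTW

def _check_band(n: int, m: int, window: int) -> None:
    if abs(n - m) > window:
        raise ValueError(
            f"series lengths {n} and {m} cannot be aligned within a "
            f"warping band of radius {window}"
        )


def dtw_distance(a, b, window: int = 1) -> float:
    """Dynamic-time-warping distance within a Sakoe-Chiba band.

    Squared-difference local cost, symmetric steps (diagonal, horizontal,
    vertical), square root of the accumulated cost returned. ``window`` is
    the band radius in index units (daily series: 1 index = 1 day).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    _check_band(n, m, window)
    acc = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(max(0, i - window), min(m, i + window + 1)):
            c = (a[i] - b[j]) ** 2
            if i == 0 and j == 0:
                acc[i, j] = c
            else:
                prev = min(
                    acc[i - 1, j] if i > 0 else np.inf,
                    acc[i, j - 1] if j > 0 else np.inf,
                    acc[i - 1, j - 1] if i > 0 and j > 0 else np.inf,
                )
                acc[i, j] = c + prev
    return float(np.sqrt(acc[n - 1, m - 1]))


def dtw_path(a, b, window: int = 1):
    """DTW distance plus one optimal alignment path (list of index pairs).

    Ties among predecessors are broken preferring diagonal, then vertical,
    then horizontal steps, making the path deterministic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    _check_band(n, m, window)
    acc = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(max(0, i - window), min(m, i + window + 1)):
            c = (a[i] - b[j]) ** 2
            if i == 0 and j == 0:
                acc[i, j] = c
                continue
            prev = min(
                acc[i - 1, j - 1] if i > 0 and j > 0 else np.inf,
                acc[i - 1, j] if i > 0 else np.inf,
                acc[i, j - 1] if j > 0 else np.inf,
            )
            acc[i, j] = c + prev
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        options = []
        if i > 0 and j > 0:
            options.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            options.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            options.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(options, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return float(np.sqrt(acc[n - 1, m - 1])), path


def pairwise_dtw(X: np.ndarray, window: int = 1) -> np.ndarray:
    """All-pairs DTW distance matrix, band DP vectorized across pairs.

    Runs the same recursion as :func:`dtw_distance` but carries one
    (G, G) matrix of accumulated costs per band cell, so the whole distance
    matrix is produced with O(T * window) numpy operations.
    """
    X = np.asarray(X, dtype=float)
    G, T = X.shape
    prev: dict[int, np.ndarray] = {}
    for i in range(T):
        cur: dict[int, np.ndarray] = {}
        for j in range(max(0, i - window), min(T, i + window + 1)):
            c = np.subtract.outer(X[:, i], X[:, j]) ** 2
            if i == 0 and j == 0:
                cur[j] = c
                continue
            best = None
            for cand in (prev.get(j), cur.get(j - 1), prev.get(j - 1)):
                if cand is not None:
                    best = cand if best is None else np.minimum(best, cand)
            cur[j] = c + best
        prev = cur
    return np.sqrt(prev[T - 1])


# --------------------------------------------------------------------- DBA

def dba_centroid(series: np.ndarray, window: int = 1, max_iter: int = 10,
                 dists: np.ndarray | None = None) -> np.ndarray:
    """DTW barycenter average of a set of equal-length series.

    Initialized at the medoid; each iteration aligns every series to the
    current centroid and re-averages the values mapped to each centroid
    index. The objective (sum of squared DTW distances to the centroid) is
    non-increasing: an update that fails to improve it is discarded and
    iteration stops.
    """
    S = np.atleast_2d(np.asarray(series, dtype=float))
    N, T = S.shape
    if N == 0:
        raise ValueError("empty series set")
    if N == 1:
        return S[0].copy()
    if dists is None:
        dists = pairwise_dtw(S, window=window)
    medoid = int(np.argmin((dists**2).sum(axis=1)))
    centroid = S[medoid].copy()

    def objective(c):
        return sum(dtw_distance(c, s, window=window) ** 2 for s in S)

    obj = objective(centroid)
    for _ in range(max_iter):
        sums = np.zeros(T)
        counts = np.zeros(T)
        for s in S:
            _, path = dtw_path(centroid, s, window=window)
            for i, j in path:
                sums[i] += s[j]
                counts[i] += 1
        new = sums / counts
        new_obj = objective(new)
        if new_obj >= obj - 1e-12:
            break
        centroid, obj = new, new_obj
    return centroid


# ---------------------------------------------------------------- clusters

_SHAPE_ORDER = ("up", "down", "early_peak", "late_peak", "mid_trough")


def _shape_templates(ages: np.ndarray) -> np.ndarray:
    """Z-scored canonical shapes on the observed age grid, rows in label
    order 1..5 (up, down, early peak, late peak, mid trough)."""
    rows = []
    for a in _SHAPE_ORDER:
        f = archetype_profile(a, ages)
        rows.append((f - f.mean()) / f.std())
    return np.stack(rows)


def label_by_shape(centroids: list, ages: np.ndarray) -> dict:
    """Map raw cluster indices to semantic labels 1-5 by template match.

    With exactly five centroids the assignment is the correlation-maximizing
    bijection; otherwise each centroid independently takes its best-matching
    template's label.
    """
    templates = _shape_templates(ages)
    C = np.stack(centroids)
    Cz = (C - C.mean(axis=1, keepdims=True))
    sd = Cz.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Cz /= sd
    corr = Cz @ templates.T / len(ages)
    if len(centroids) == len(_SHAPE_ORDER):
        rows, cols = linear_sum_assignment(-corr)
        return {int(r): int(c) + 1 for r, c in zip(rows, cols)}
    return {i: int(np.argmax(corr[i])) + 1 for i in range(len(centroids))}


def cluster_trajectories(T: TrajectoryMatrix, age_dge: pd.DataFrame,
                         k: int = 5, alpha0: float = 0.01,
                         window: int = 1) -> ClusterAssignment:
    """Cluster standardized trajectories into cluster 0 plus k shape clusters.

    Genes with no age coefficient (age1..age3) significant at q < alpha0 in
    the chronological-age model go to cluster 0. The rest are clustered by
    complete linkage on pairwise DTW distances, the tree is cut into k
    clusters, DBA centroids are computed, and clusters are relabeled by
    centroid shape.
    """
    if not T.standardized:
        raise ValueError("trajectories must be standardized before clustering")
    qcols = [c for c in ("q_age1", "q_age2", "q_age3") if c in age_dge.columns]
    if not qcols:
        raise ValueError("age DGE table lacks q_age1..q_age3 columns")
    q = age_dge.loc[T.values.index, qcols]
    significant = (q < alpha0).any(axis=1).fillna(False)

    labels = pd.Series(0, index=T.values.index, name="cluster", dtype=int)
    clusterable = T.values.index[significant]
    if len(clusterable) < k:
        raise ValueError(f"only {len(clusterable)} age-significant genes; "
                         f"cannot cut into {k} clusters")
    Z = T.values.loc[clusterable].to_numpy()
    D = pairwise_dtw(Z, window=window)
    # guard tiny negative asymmetries from float noise before condensing
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    link = linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(link, t=k, criterion="maxclust")

    centroids_raw = []
    for c in range(1, raw.max() + 1):
        members = Z[raw == c]
        sub = D[np.ix_(raw == c, raw == c)]
        centroids_raw.append(dba_centroid(members, window=window, dists=sub))
    mapping = label_by_shape(centroids_raw, T.ages)
    labels.loc[clusterable] = [mapping[c - 1] for c in raw]
    centroids = {mapping[i]: centroids_raw[i] for i in range(len(centroids_raw))}
    return ClusterAssignment(labels=labels, centroids=centroids,
                             linkage=link, ages=T.ages)
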