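"""Temporal K-means segmentation of ERP topographies.

Grand-average topographies — one sample per (condition, time point), features
the raw amplitudes of all electrodes — are clustered with K-means.  K is
chosen by a baseline-split stopping rule: prestimulus topographies are
assumed to reflect a single resting pattern, so the first K at which the
baseline samples split into more than one cluster marks overfitting, and the
previous K is kept.  Clusters are then ranked by the Euclidean distance of
their centroid to the baseline cluster's centroid (baseline = rank 1), giving
a baseline-relative ordering of the segmented processing stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import ERPSet

__all__ = [
    "TopographySampleMatrix",
    "ClusterSolution",
    "build_samples",
    "kmeans_fit",
    "select_k",
    "rank_clusters",
    "baseline_mask_from_meta",
    "solution_table",
]

DEFAULT_K_MAX = 12
DEFAULT_RESTARTS = 50


@dataclass
class TopographySampleMatrix:
    """samples x channels matrix with (condition, time_ms) metadata rows."""

    X: np.ndarray
    meta: pd.DataFrame  # columns: condition, time_ms
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be samples x channels")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows must match sample count")
        if self.X.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterSolution:
    K: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    restarts: int
    baseline_cluster_id: int | None = None
    ranks: np.ndarray | None = None  # rank per cluster id, 1..K

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not (0 <= self.labels.min()
                                     and self.labels.max() < self.K):
            raise ValueError("labels out of [0, K)")
        if self.inertia < 0:
            raise ValueError("inertia must be nonnegative")
        if self.ranks is not None:
            r = np.sort(np.asarray(self.ranks))
            if not np.array_equal(r, np.arange(1, self.K + 1)):
                raise ValueError("ranks must be a permutation of 1..K")


def build_samples(grand_erps: ERPSet,
                  time_range_ms: tuple[float, float] | None = None
                  ) -> TopographySampleMatrix:
    """Stack every (condition, time point) topography into sample rows.

    ``time_range_ms`` restricts to [lo, hi) on the grand-average time axis;
    by default the full epoch is used.
    """
    t = grand_erps.time_ms
    if time_range_ms is None:
        tmask = np.ones(t.size, dtype=bool)
    else:
        lo, hi = time_range_ms
        tmask = (t >= lo) & (t < hi)
    if not tmask.any():
        raise ValueError("time range selects no samples")
    rows, conds, times = [], [], []
    for cond, erp in grand_erps.erps.items():
        rows.append(erp[:, tmask].T)
        conds.extend([cond] * int(tmask.sum()))
        times.extend(t[tmask].tolist())
    X = np.vstack(rows)
    meta = pd.DataFrame({"condition": conds, "time_ms": times})
    return TopographySampleMatrix(X=X, meta=meta,
                                  channel_names=grand_erps.montage.channel_names)


def baseline_mask_from_meta(m: TopographySampleMatrix) -> np.ndarray:
    """Prestimulus samples (t < 0 ms) of every condition, pooled."""
    return (m.meta["time_ms"].to_numpy() < 0.0)


def kmeans_fit(m: TopographySampleMatrix, K: int, seed: int = 0,
               restarts: int = DEFAULT_RESTARTS) -> ClusterSolution:
    """Best-of-restarts K-means (k-means++ seeding, Lloyd iterations)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_samples:
        raise ValueError(f"K={K} exceeds n_samples={m.n_samples}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=restarts,
                max_iter=300, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(m.X)
    return ClusterSolution(K=K, labels=labels, centroids=km.cluster_centers_,
                           inertia=float(km.inertia_), seed=seed,
                           restarts=restarts)


def select_k(m: TopographySampleMatrix, baseline_mask: np.ndarray,
             seed: int = 0, k_max: int = DEFAULT_K_MAX,
             restarts: int = DEFAULT_RESTARTS,
             baseline_purity: float = 1.0,
             return_break: bool = False) -> tuple[int, ClusterSolution]:
    """Choose K by the baseline-split stopping rule.

    K starts at 2 and increases while the baseline samples stay in a single
    cluster; the first K whose solution splits the baseline (``K_break``)
    stops the search and ``K* = K_break - 1`` is returned with its fit.
    ``baseline_purity`` relaxes "single cluster" to a modal fraction (default
    1.0 = strict); ``return_break=True`` returns ``K_break`` itself instead
    (the alternative reading of the stopping rule).
    """
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.shape != (m.n_samples,):
        raise ValueError("baseline_mask must have one entry per sample")
    if not baseline_mask.any():
        raise ValueError("baseline_mask selects no samples")
    if not 0.0 < baseline_purity <= 1.0:
        raise ValueError("baseline_purity must be in (0, 1]")

    prev: ClusterSolution | None = None
    for K in range(2, k_max + 1):
        sol = kmeans_fit(m, K, seed=seed, restarts=restarts)
        base_labels = sol.labels[baseline_mask]
        counts = np.bincount(base_labels, minlength=K)
        modal_frac = counts.max() / base_labels.size
        if modal_frac < baseline_purity:  # baseline split at this K
            if return_break:
                return K, sol
            if prev is None:
                warnings.warn("baseline splits already at K=2; returning the "
                              "degenerate single-cluster solution",
                              stacklevel=2)
                centroid = m.X.mean(axis=0, keepdims=True)
                inertia = float(((m.X - centroid) ** 2).sum())
                return 1, ClusterSolution(
                    K=1, labels=np.zeros(m.n_samples, dtype=int),
                    centroids=centroid, inertia=inertia, seed=seed,
                    restarts=restarts)
            return K - 1, prev
        prev = sol
    warnings.warn(f"baseline never split: K search cap {k_max} reached",
                  stacklevel=2)
    assert prev is not None
    return k_max, prev


def rank_clusters(sol: ClusterSolution,
                  baseline_mask: np.ndarray) -> ClusterSolution:
    """Rank clusters by centroid distance to the baseline cluster.

    The baseline cluster is the modal label of the baseline samples and gets
    rank 1; remaining clusters are ranked by ascending Euclidean distance of
    their centroid to the baseline centroid, ties broken by cluster id.
    """
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    base_labels = sol.labels[baseline_mask]
    if base_labels.size == 0:
        raise ValueError("baseline_mask selects no samples")
    counts = np.bincount(base_labels, minlength=sol.K)
    base_id = int(np.argmax(counts))
    dists = np.linalg.norm(sol.centroids - sol.centroids[base_id], axis=1)
    dists[base_id] = -np.inf  # baseline always first
    order = np.lexsort((np.arange(sol.K), dists))  # distance, then id
    ranks = np.empty(sol.K, dtype=int)
    ranks[order] = np.arange(1, sol.K + 1)
    return replace(sol, baseline_cluster_id=base_id, ranks=ranks)


def solution_table(m: TopographySampleMatrix,
                   sol: ClusterSolution) -> pd.DataFrame:
    """Tidy per-sample table: condition, time_ms, label, rank."""
    df = m.meta.copy()
    df["label"] = sol.labels
    if sol.ranks is not None:
        df["rank"] = sol.ranks[sol.labels]
    return df
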