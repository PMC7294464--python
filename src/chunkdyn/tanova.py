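"""TANOVA: topographic pattern tests with a permutation null and
cluster-based temporal correction.

The dissimilarity between two scalp topographies u, v is the cosine distance
``d = 1 - u.v / (|u||v|)``, ranging from 0 (identical patterns) to 2 (exactly
opposite patterns) and invariant to overall response magnitude.  For each
10-ms window, d is computed between the two conditions' grand-mean
topographies (mean over subjects, mean over window samples).  The null
distribution shuffles the two condition labels independently within each
subject (a fair-coin swap), recomputes d, and yields the one-sided
permutation p-value with the add-one estimator ``(b+1)/(m+1)``.

Multiple windows are corrected with a cluster-based permutation scheme:
contiguous runs of windows with p below the precluster threshold (0.1) form
temporal clusters whose mass is the sum of observed d; each shuffle's maximal
cluster mass (computed from that shuffle's own window-wise p against the
ensemble) builds the max-statistic null, and a cluster is significant when
its corrected p is at or below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ERPSet

__all__ = [
    "TanovaConfig",
    "TemporalCluster",
    "TanovaResult",
    "cosine_distance",
    "tanova_window",
    "tanova_series",
    "cluster_correct",
    "pooled_comparison",
    "null_familywise_error_rate",
]


@dataclass(frozen=True)
class TanovaConfig:
    window_ms: float = 10.0
    n_shuffles: int = 1000
    precluster_p: float = 0.1
    corrected_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0.0 < self.precluster_p < 1.0:
            raise ValueError("precluster_p must be in (0, 1)")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")


@dataclass(frozen=True)
class TemporalCluster:
    start_ms: float
    end_ms: float
    mass: float
    p_corrected: float | None = None
    significant: bool = False


@dataclass
class TanovaResult:
    window_starts_ms: np.ndarray
    window_ms: float
    d_obs: np.ndarray
    p: np.ndarray
    config: TanovaConfig
    clusters: list[TemporalCluster] = field(default_factory=list)
    null_max_mass: np.ndarray | None = None
    d_null: np.ndarray | None = None  # shuffles x windows, kept for correction

    @property
    def n_windows(self) -> int:
        return self.d_obs.size

    def earliest_significant_onset_ms(self) -> float | None:
        """Start of the earliest significant corrected cluster, if any."""
        sig = [c.start_ms for c in self.clusters if c.significant]
        return min(sig) if sig else None


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cos(angle(u, v))``: 0 for identical patterns, 1 for orthogonal,
    2 for sign-inverted; invariant to positive scaling of either map."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("u and v must be equal-length vectors of size >= 2")
    uu, vv = np.dot(u, u), np.dot(v, v)
    if uu == 0 or vv == 0:
        raise ValueError("cosine distance undefined for a zero topography")
    # sqrt(uu * vv) rather than |u|*|v|: identical maps then cancel exactly;
    # clip removes rounding outside the mathematical range [0, 2]
    return float(np.clip(1.0 - np.dot(u, v) / np.sqrt(uu * vv), 0.0, 2.0))


def _window_grid(time_range_ms: tuple[float, float],
                 window_ms: float) -> np.ndarray:
    lo, hi = time_range_ms
    span = hi - lo
    n_win = span / window_ms
    if abs(n_win - round(n_win)) > 1e-9 or round(n_win) < 1:
        raise ValueError(f"window {window_ms} ms does not tile "
                         f"range [{lo}, {hi}) ms")
    return lo + np.arange(int(round(n_win))) * window_ms


def _subject_window_means(subj_erps: list[ERPSet], cond: str,
                          window_starts: np.ndarray,
                          window_ms: float) -> np.ndarray:
    """(n_subjects, n_windows, n_channels) mean topography per window."""
    out = []
    for erp in subj_erps:
        if cond not in erp.erps:
            raise ValueError(f"subject {erp.subject_id!r} is missing "
                             f"condition {cond!r}")
        t = erp.time_ms
        arr = erp.erps[cond]  # channels x samples
        wins = []
        for ws in window_starts:
            mask = (t >= ws) & (t < ws + window_ms)
            if not mask.any():
                raise ValueError(f"window [{ws}, {ws + window_ms}) ms holds "
                                 "no samples")
            wins.append(arr[:, mask].mean(axis=1))
        out.append(np.stack(wins))
    return np.stack(out)


def _cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise cosine distance for (..., n_channels) stacks."""
    num = np.einsum("...c,...c->...", A, B)
    den = np.sqrt(np.einsum("...c,...c->...", A, A)
                  * np.einsum("...c,...c->...", B, B))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.clip(1.0 - num / den, 0.0, 2.0)
    return np.where(den == 0, np.nan, d)


def _null_distances(WA: np.ndarray, WB: np.ndarray,
                    swaps: np.ndarray) -> np.ndarray:
    """Cosine distance per (shuffle, window) under within-subject swaps.

    WA/WB: (n_subj, n_win, n_ch); swaps: (n_shuffles, n_subj) in {0,1}.
    """
    n_subj = WA.shape[0]
    flatA = WA.reshape(n_subj, -1)
    flatB = WB.reshape(n_subj, -1)
    keep = 1.0 - swaps
    meanA = (keep @ flatA + swaps @ flatB) / n_subj
    meanB = (swaps @ flatA + keep @ flatB) / n_subj
    shp = (swaps.shape[0],) + WA.shape[1:]
    return _cosine_rows(meanA.reshape(shp), meanB.reshape(shp))


def tanova_window(subj_erps: list[ERPSet], cond_a: str, cond_b: str,
                  window: tuple[float, float],
                  cfg: TanovaConfig = TanovaConfig()) -> tuple[float, float]:
    """Observed cosine distance and permutation p for one time window."""
    lo, hi = window
    res = tanova_series(subj_erps, cond_a, cond_b, (lo, hi),
                        TanovaConfig(window_ms=hi - lo,
                                     n_shuffles=cfg.n_shuffles,
                                     precluster_p=cfg.precluster_p,
                                     corrected_alpha=cfg.corrected_alpha,
                                     seed=cfg.seed))
    return float(res.d_obs[0]), float(res.p[0])


def tanova_series(subj_erps: list[ERPSet], cond_a: str, cond_b: str,
                  time_range_ms: tuple[float, float],
                  cfg: TanovaConfig = TanovaConfig()) -> TanovaResult:
    """Windowed TANOVA over a time range (uncorrected p per window).

    One shuffle sequence is shared by every window so that
    :func:`cluster_correct` can reuse the stored per-shuffle statistics.
    """
    window_starts = _window_grid(time_range_ms, cfg.window_ms)
    WA = _subject_window_means(subj_erps, cond_a, window_starts, cfg.window_ms)
    WB = _subject_window_means(subj_erps, cond_b, window_starts, cfg.window_ms)

    d_obs = _cosine_rows(WA.mean(axis=0), WB.mean(axis=0))
    rng = np.random.default_rng(cfg.seed)
    swaps = (rng.random((cfg.n_shuffles, WA.shape[0])) < 0.5).astype(float)
    d_null = _null_distances(WA, WB, swaps)
    # round so permutation ties are exact despite float rounding
    d_obs = np.round(d_obs, 12)
    d_null = np.round(d_null, 12)

    m = cfg.n_shuffles
    p = (np.sum(d_null >= d_obs[None, :], axis=0) + 1.0) / (m + 1.0)
    return TanovaResult(window_starts_ms=window_starts, window_ms=cfg.window_ms,
                        d_obs=d_obs, p=p, config=cfg, d_null=d_null)


def _clusters_from_mask(mask: np.ndarray,
                        stat: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of True: (start index, stop index, mass)."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j, float(stat[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def cluster_correct(series: TanovaResult,
                    cfg: TanovaConfig | None = None) -> TanovaResult:
    """Cluster-based correction over the temporal dimension.

    Observed clusters are runs of windows with p below the precluster
    threshold; mass is the summed observed d.  The null max-mass distribution
    is built per shuffle: that shuffle's window-wise p is computed against
    the full shuffle ensemble, clusters are formed the same way on its own d
    values, and the maximal mass (0 when no cluster forms) is recorded.
    """
    cfg = cfg or series.config
    if series.d_null is None:
        raise ValueError("series lacks stored shuffle statistics; recompute "
                         "with tanova_series before correcting")
    D = series.d_null  # (m, n_win)
    m = D.shape[0]

    obs_clusters = _clusters_from_mask(series.p < cfg.precluster_p,
                                       series.d_obs)

    # per-shuffle window-wise p against the pooled ensemble {observed,
    # shuffles}: every member (itself included) is counted identically, the
    # exact exchangeable analogue of the observed (b+1)/(m+1) formula
    count_ge = np.empty_like(D)
    for w in range(D.shape[1]):
        col_sorted = np.sort(D[:, w])
        count_ge[:, w] = m - np.searchsorted(col_sorted, D[:, w], side="left")
    P_null = (count_ge + (series.d_obs[None, :] >= D)) / (m + 1.0)

    max_mass = np.zeros(m)
    below = P_null < cfg.precluster_p
    for s in range(m):
        cl = _clusters_from_mask(below[s], D[s])
        if cl:
            max_mass[s] = max(c[2] for c in cl)

    clusters = []
    for (i, j, mass) in obs_clusters:
        p_corr = (np.sum(max_mass >= mass) + 1.0) / (m + 1.0)
        clusters.append(TemporalCluster(
            start_ms=float(series.window_starts_ms[i]),
            end_ms=float(series.window_starts_ms[j] + series.window_ms),
            mass=mass, p_corrected=float(p_corr),
            significant=bool(p_corr <= cfg.corrected_alpha)))
    return TanovaResult(window_starts_ms=series.window_starts_ms,
                        window_ms=series.window_ms, d_obs=series.d_obs,
                        p=series.p, config=cfg, clusters=clusters,
                        null_max_mass=max_mass, d_null=series.d_null)


def pooled_comparison(subj_erps: list[ERPSet], single_cond: str,
                      pooled_conds: list[str],
                      time_range_ms: tuple[float, float],
                      cfg: TanovaConfig = TanovaConfig()) -> TanovaResult:
    """Compare one condition against the per-subject average of several
    others (corrected series)."""
    if single_cond in pooled_conds:
        raise ValueError(f"{single_cond!r} cannot be in the pooled set")
    pooled_label = "+".join(pooled_conds)
    pseudo = []
    for erp in subj_erps:
        missing = [c for c in [single_cond, *pooled_conds]
                   if c not in erp.erps]
        if missing:
            raise ValueError(f"subject {erp.subject_id!r} missing {missing}")
        mean_map = np.mean([erp.erps[c] for c in pooled_conds], axis=0)
        pseudo.append(ERPSet(
            montage=erp.montage,
            erps={single_cond: erp.erps[single_cond], pooled_label: mean_map},
            n_trials_used={single_cond: erp.n_trials_used[single_cond],
                           pooled_label: 1},
            time_ms=erp.time_ms, subject_id=erp.subject_id))
    series = tanova_series(pseudo, single_cond, pooled_label,
                           time_range_ms, cfg)
    return cluster_correct(series, cfg)


def null_familywise_error_rate(n_datasets: int = 200, n_subjects: int = 12,
                               n_shuffles: int = 199,
                               time_range_ms: tuple[float, float] = (0.0,
                                                                     600.0),
                               seed: int = 0,
                               montage=None) -> float:
    """Familywise false-positive rate of the corrected procedure under the
    null.

    Simulates datasets whose two conditions share one generating distribution
    (correlated-noise subject ERPs), runs the windowed TANOVA with
    cluster-based correction, and returns the fraction of datasets with at
    least one significant corrected cluster — the quantity that should stay
    at or below the corrected alpha.
    """
    from .data import standard_montage_32
    from .synth import simulate_null_erps

    montage = montage or standard_montage_32()
    root = np.random.SeedSequence(seed)
    data_seeds = root.spawn(n_datasets)
    hits = 0
    for r in range(n_datasets):
        s1, s2 = (int(x % (2 ** 31))
                  for x in data_seeds[r].generate_state(2))
        erps = simulate_null_erps(n_subjects, montage, time_range_ms,
                                  seed=s1)
        cfg = TanovaConfig(window_ms=10.0, n_shuffles=n_shuffles, seed=s2)
        res = cluster_correct(
            tanova_series(erps, "A", "B", time_range_ms, cfg), cfg)
        hits += any(c.significant for c in res.clusters)
    return hits / n_datasets
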