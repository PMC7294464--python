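"""Mass-univariate amplitude tests: electrode-wise paired t in 20-ms windows
with Benjamini-Hochberg FDR across the electrode family of each window, plus
pointwise channel waveform tests and onset extraction.

No correction is applied across time windows — a deliberately liberal choice
that trades Type I control on the time axis for sensitivity to the earliest
amplitude difference (the quantity of interest here is the onset, and missing
it is the costlier error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ERPSet

__all__ = [
    "WindowTestResult",
    "OnsetReport",
    "window_means",
    "paired_t_map",
    "fdr_bh",
    "fdr_correct",
    "channel_waveform_test",
    "detect_onset",
    "pool_conditions",
]


@dataclass
class WindowTestResult:
    """Per (window, electrode) statistics of a paired amplitude comparison."""

    window_starts_ms: np.ndarray
    window_ms: float
    channel_names: tuple[str, ...]
    diff_uv: np.ndarray       # windows x electrodes, mean(a) - mean(b)
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    level: float | None = None
    degenerate: np.ndarray | None = None  # zero-variance, nonzero-diff cells


@dataclass
class OnsetReport:
    """Earliest window with any significant electrode."""

    onset_ms: float | None
    electrodes: tuple[str, ...] = ()

    @property
    def found(self) -> bool:
        return self.onset_ms is not None


def window_means(subj_erps: list[ERPSet], conditions: list[str] | None = None,
                 window_ms: float = 20.0,
                 time_range_ms: tuple[float, float] = (0.0, 600.0)
                 ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-subject window-mean amplitudes.

    Returns ``(means, window_starts)`` where ``means[cond]`` is
    (n_subjects, n_windows, n_electrodes) and windows are half-open
    ``[start, start + window)``, tiling the range exactly.
    """
    lo, hi = time_range_ms
    n_win = (hi - lo) / window_ms
    if abs(n_win - round(n_win)) > 1e-9 or round(n_win) < 1:
        raise ValueError(f"window {window_ms} ms does not tile "
                         f"range [{lo}, {hi}) ms")
    starts = lo + np.arange(int(round(n_win))) * window_ms
    if conditions is None:
        conditions = subj_erps[0].conditions
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        per_subj = []
        for erp in subj_erps:
            if cond not in erp.erps:
                raise ValueError(f"subject {erp.subject_id!r} missing "
                                 f"condition {cond!r}")
            t = erp.time_ms
            arr = erp.erps[cond]
            wins = [arr[:, (t >= ws) & (t < ws + window_ms)].mean(axis=1)
                    for ws in starts]
            per_subj.append(np.stack(wins))
        out[cond] = np.stack(per_subj)
    return out, starts


def paired_t_map(means: dict[str, np.ndarray], cond_a: str, cond_b: str,
                 window_starts_ms: np.ndarray,
                 window_ms: float = 20.0,
                 channel_names: tuple[str, ...] = ()) -> WindowTestResult:
    """Paired t across subjects for every (window, electrode) cell.

    Two-sided p from the t distribution with n-1 df.  Cells with zero
    difference variance get t=0, p=1 when all differences are zero, and are
    flagged degenerate (p=0) otherwise.
    """
    A, B = means[cond_a], means[cond_b]
    if A.shape[0] < 2:
        raise ValueError("paired t needs >= 2 subjects")
    diffs = A - B  # subjects x windows x electrodes
    n = diffs.shape[0]
    mean_d = diffs.mean(axis=0)
    sd_d = diffs.std(axis=0, ddof=1)
    degenerate = (sd_d == 0) & (mean_d != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    t = np.where(sd_d == 0, np.where(mean_d == 0, 0.0, np.inf * np.sign(mean_d)),
                 t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    return WindowTestResult(window_starts_ms=np.asarray(window_starts_ms),
                            window_ms=window_ms,
                            channel_names=tuple(channel_names),
                            diff_uv=mean_d, t=t, p=p, degenerate=degenerate)


def fdr_bh(p_values: np.ndarray, level: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns ``(significant mask, q values)``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, q


def fdr_correct(res: WindowTestResult,
                level: float = 0.05) -> WindowTestResult:
    """Apply BH within each window's electrode family (never across time)."""
    q = np.empty_like(res.p)
    sig = np.empty(res.p.shape, dtype=bool)
    for w in range(res.p.shape[0]):
        sig[w], q[w] = fdr_bh(res.p[w], level=level)
    res.q = q
    res.significant = sig
    res.level = level
    return res


def channel_waveform_test(subj_erps: list[ERPSet], cond_a: str, cond_b: str,
                          channels: tuple[str, ...] = ("P3", "P4"),
                          alpha: float = 0.05
                          ) -> dict[str, dict[str, np.ndarray | list]]:
    """Pointwise paired t on selected channels (uncorrected).

    For each channel returns t and p series over the full epoch plus the
    contiguous runs of p < alpha as (start ms, end ms) shading intervals.
    """
    if len(subj_erps) < 2:
        raise ValueError("paired test undefined for a single subject")
    montage = subj_erps[0].montage
    idx = {c: montage.index(c) for c in channels}  # KeyError if unknown
    t_axis = subj_erps[0].time_ms
    out: dict[str, dict] = {}
    for c, ci in idx.items():
        a = np.stack([e.erps[cond_a][ci] for e in subj_erps])
        b = np.stack([e.erps[cond_b][ci] for e in subj_erps])
        tt = stats.ttest_rel(a, b, axis=0)
        p = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
        below = p < alpha
        runs = []
        i = 0
        while i < below.size:
            if below[i]:
                j = i
                while j + 1 < below.size and below[j + 1]:
                    j += 1
                runs.append((float(t_axis[i]), float(t_axis[j])))
                i = j + 1
            else:
                i += 1
        out[c] = {"time_ms": t_axis,
                  "t": np.where(np.isnan(tt.statistic), 0.0, tt.statistic),
                  "p": p, "intervals": runs}
    return out


def detect_onset(res: WindowTestResult,
                 min_consecutive_windows: int = 1) -> OnsetReport:
    """Earliest window (ascending time) with >= 1 significant electrode.

    Because no correction runs across time, isolated false-positive windows
    occur at roughly the per-window alpha rate; ``min_consecutive_windows=2``
    reads the onset from the earliest sustained run instead, which isolated
    flukes essentially never start.
    """
    if res.significant is None:
        raise ValueError("run fdr_correct before onset detection")
    order = np.argsort(res.window_starts_ms)
    any_sig = res.significant[order].any(axis=1)
    for i, w in enumerate(order):
        if i + min_consecutive_windows <= order.size \
                and any_sig[i:i + min_consecutive_windows].all():
            chans = tuple(np.asarray(res.channel_names)[res.significant[w]]) \
                if res.channel_names else ()
            return OnsetReport(onset_ms=float(res.window_starts_ms[w]),
                               electrodes=chans)
    return OnsetReport(onset_ms=None)


def pool_conditions(subj_erps: list[ERPSet],
                    groups: dict[str, list[str]]) -> list[ERPSet]:
    """Per-subject average of member conditions into pooled pseudo-conditions
    (e.g. ``{"Gw": ["GwLw", "GwLn"], "Gn": ["GnLw", "GnLn"]}``)."""
    out = []
    for erp in subj_erps:
        erps, n_used = {}, {}
        for name, members in groups.items():
            missing = [m for m in members if m not in erp.erps]
            if missing:
                raise ValueError(f"subject {erp.subject_id!r} missing "
                                 f"{missing}")
            erps[name] = np.mean([erp.erps[m] for m in members], axis=0)
            n_used[name] = min(erp.n_trials_used[m] for m in members)
        out.append(ERPSet(montage=erp.montage, erps=erps,
                          n_trials_used=n_used, time_ms=erp.time_ms,
                          subject_id=erp.subject_id))
    return out
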