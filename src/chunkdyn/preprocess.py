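"""Preprocessing: FIR bandpass, epoching, baseline correction, threshold
artifact rejection, average reference, per-condition ERPs and RMS.

The default chain mirrors a conventional ERP pipeline: 0.1-30 Hz
Hamming-windowed sinc FIR filter (zero-phase by group-delay compensation),
epochs -200..800 ms around stimulus onset, baseline correction over the
200 ms prestimulus interval, rejection of any trial whose amplitude exceeds
+-50 uV anywhere in the epoch, then average re-referencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .data import ContinuousRecording, EpochSet, ERPSet

__all__ = [
    "PreprocConfig",
    "RejectionLog",
    "design_bandpass",
    "bandpass_fir",
    "rereference_average",
    "epoch_and_baseline",
    "reject_artifacts",
    "average_erp",
    "rms",
    "preprocess_epochs",
]


@dataclass(frozen=True)
class PreprocConfig:
    low_hz: float = 0.1
    high_hz: float = 30.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float = 50.0
    reject_channels: tuple[str, ...] | None = None  # None = all channels

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low < high")
        lo, hi = self.epoch_window_ms
        blo, bhi = self.baseline_window_ms
        if not (lo <= blo < bhi <= hi):
            raise ValueError("baseline window must lie inside epoch window")
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class RejectionLog:
    """Per-trial outcome of threshold artifact rejection."""

    keep: np.ndarray                       # bool per input trial
    offending: list[tuple[int, str, int]]  # (trial, channel name, sample)
    threshold_uv: float

    @property
    def n_total(self) -> int:
        return self.keep.size

    @property
    def n_dropped(self) -> int:
        return int((~self.keep).sum())

    @property
    def fraction_dropped(self) -> float:
        return self.n_dropped / self.n_total if self.n_total else 0.0


def design_bandpass(low_hz: float, high_hz: float, srate: float) -> np.ndarray:
    """Hamming-windowed sinc FIR bandpass taps.

    Transition bandwidth ``min(max(0.25*low, 2 Hz), high/4)``, additionally
    capped at the low cutoff itself — a transition wider than the cutoff
    leaves no stop-band, so a 0.1 Hz edge forces a narrow (0.1 Hz) transition
    and hence a long filter.  Order follows the Hamming rule of thumb
    (normalized width 3.3 / numtaps), rounded up to odd so group delay is an
    integer number of samples.
    """
    nyq = srate / 2.0
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    tb = min(max(0.25 * low_hz, 2.0), high_hz / 4.0, low_hz)
    numtaps = int(np.ceil(3.3 * srate / tb))
    if numtaps % 2 == 0:
        numtaps += 1
    return sp_signal.firwin(numtaps, [low_hz, high_hz], fs=srate,
                            pass_zero=False, window="hamming")


def bandpass_fir(x: ContinuousRecording,
                 cfg: PreprocConfig = PreprocConfig()) -> ContinuousRecording:
    """Zero-phase bandpass: forward FIR filtering with group-delay
    compensation (the filter is linear-phase, so shifting by (numtaps-1)/2
    samples realigns the output)."""
    taps = design_bandpass(cfg.low_hz, cfg.high_hz, x.srate)
    if x.n_samples <= taps.size:
        raise ValueError(f"signal length {x.n_samples} <= filter order "
                         f"{taps.size - 1}")
    delay = (taps.size - 1) // 2
    full = sp_signal.oaconvolve(x.data, taps[None, :], axes=1)
    y = full[:, delay:delay + x.n_samples]
    return replace(x, data=y)


def rereference_average(e: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous channel average (mean over channels
    becomes 0 at every trial and sample). Idempotent."""
    if e.montage.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    data = e.data - e.data.mean(axis=1, keepdims=True)
    return replace(e, data=data,
                   montage=replace(e.montage, reference_label="average"))


def epoch_and_baseline(x: ContinuousRecording,
                       events: list[tuple[int, str]] | None = None,
                       cfg: PreprocConfig = PreprocConfig(),
                       subject_id: str = "") -> tuple[EpochSet, list[int]]:
    """Cut epochs around events and baseline-correct each trial/channel.

    ``events`` are (onset sample, condition label); defaults to the
    recording's own event list.  Events too close to either recording edge
    are skipped; their indices are returned alongside the epochs.
    """
    if events is None:
        events = x.events
    lo, hi = cfg.epoch_window_ms
    n_pre = int(round(-lo * x.srate / 1000.0))
    n_post = int(round(hi * x.srate / 1000.0))
    n_sm = n_pre + n_post
    time_ms = (np.arange(n_sm) - n_pre) * 1000.0 / x.srate
    blo, bhi = cfg.baseline_window_ms
    bmask = (time_ms >= blo) & (time_ms < bhi)

    trials, labels, skipped = [], [], []
    for k, (onset, label) in enumerate(events):
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > x.n_samples:
            skipped.append(k)
            continue
        ep = x.data[:, start:stop].copy()
        ep -= ep[:, bmask].mean(axis=1, keepdims=True)
        trials.append(ep)
        labels.append(label)
    data = np.stack(trials) if trials else np.empty((0, x.montage.n_channels,
                                                     n_sm))
    e = EpochSet(montage=x.montage, subject_id=subject_id, data=data,
                 time_ms=time_ms, condition=np.asarray(labels, dtype=object),
                 srate=x.srate)
    return e, skipped


def reject_artifacts(e: EpochSet,
                     cfg: PreprocConfig = PreprocConfig()
                     ) -> tuple[EpochSet, RejectionLog]:
    """Drop trials whose amplitude exceeds the threshold anywhere in the
    epoch on any in-scope channel (default: all channels)."""
    if cfg.reject_channels is None:
        ch_idx = np.arange(e.montage.n_channels)
    else:
        ch_idx = np.array([e.montage.index(c) for c in cfg.reject_channels])
    absdata = np.abs(e.data[:, ch_idx, :])
    exceeded = absdata > cfg.reject_threshold_uv
    keep = ~exceeded.any(axis=(1, 2))
    offending = []
    for t in np.flatnonzero(~keep):
        flat = np.argmax(exceeded[t])
        ci, si = np.unravel_index(flat, exceeded[t].shape)
        offending.append((int(t), e.montage.channel_names[ch_idx[ci]],
                          int(si)))
    log = RejectionLog(keep=keep, offending=offending,
                       threshold_uv=cfg.reject_threshold_uv)
    kept = e.select(keep)
    if kept.n_trials == 0 and e.n_trials > 0:
        warnings.warn("artifact rejection removed every trial", stacklevel=2)
    return kept, log


def average_erp(e: EpochSet) -> ERPSet:
    """Average trials within each condition; empty conditions are omitted
    with a warning."""
    erps: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for cond in e.conditions:
        mask = e.condition == cond
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"condition {cond!r} has no trials; omitted",
                          stacklevel=2)
            continue
        erps[cond] = e.data[mask].mean(axis=0)
        n_used[cond] = n
    if not erps:
        raise ValueError("no condition has any trials to average")
    return ERPSet(montage=e.montage, erps=erps, n_trials_used=n_used,
                  time_ms=e.time_ms, subject_id=e.subject_id)


def rms(erp: ERPSet) -> dict[str, np.ndarray]:
    """Root-mean-square over channels per time point, per condition — a
    reference-free index of overall response strength."""
    return {cond: np.sqrt(np.mean(arr ** 2, axis=0))
            for cond, arr in erp.erps.items()}


def preprocess_epochs(e: EpochSet,
                      cfg: PreprocConfig = PreprocConfig()
                      ) -> tuple[EpochSet, RejectionLog]:
    """Standard epoched-data chain: baseline-correct, reject, re-reference."""
    blo, bhi = cfg.baseline_window_ms
    bmask = (e.time_ms >= blo) & (e.time_ms < bhi)
    if bmask.any():
        data = e.data - e.data[:, :, bmask].mean(axis=2, keepdims=True)
        e = replace(e, data=data)
    else:
        warnings.warn("epoch has no samples in the baseline window; "
                      "baseline correction skipped", stacklevel=2)
    kept, log = reject_artifacts(e, cfg)
    return rereference_average(kept), log
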