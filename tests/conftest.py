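import numpy as np
import pytest

from chunkdyn.data import ERPSet, Montage, standard_montage_32


@pytest.fixture
def montage8() -> Montage:
    return Montage(channel_names=("Fp1", "Fp2", "C3", "C4", "P3", "P4",
                                  "O1", "O2"),
                   eog_channels=("Fp1", "Fp2"))


@pytest.fixture
def montage32() -> Montage:
    return standard_montage_32()


def make_subject_erps(n_subjects: int, montage: Montage,
                      time_range_ms=(0.0, 600.0), srate=500.0,
                      noise_sd=1.0, seed=0,
                      pattern=None, pattern_window_ms=None,
                      pattern_amp=0.0, conditions=("A", "B"),
                      pattern_cond="B"):
    """Subject-level ERPs: iid noise per condition, optionally with a fixed
    scalp pattern added to one condition inside a time window."""
    rng = np.random.default_rng(seed)
    lo, hi = time_range_ms
    n_sm = int(round((hi - lo) * srate / 1000.0))
    t = lo + np.arange(n_sm) * 1000.0 / srate
    out = []
    for s in range(n_subjects):
        erps = {}
        for cond in conditions:
            arr = noise_sd * rng.standard_normal((montage.n_channels, n_sm))
            if (pattern is not None and cond == pattern_cond
                    and pattern_amp != 0.0):
                wlo, whi = pattern_window_ms
                mask = (t >= wlo) & (t < whi)
                arr[:, mask] += pattern_amp * np.asarray(pattern)[:, None]
            erps[cond] = arr
        out.append(ERPSet(montage=montage, erps=erps,
                          n_trials_used={c: 1 for c in conditions},
                          time_ms=t, subject_id=f"sub-{s + 1:02d}"))
    return out
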