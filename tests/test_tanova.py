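"""Cosine-distance TANOVA: statistic properties, permutation null,
cluster-based temporal correction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from chunkdyn.tanova import (TanovaConfig, cluster_correct, cosine_distance,
                             pooled_comparison, tanova_series, tanova_window)
from tests.conftest import make_subject_erps


def _nonzero_vectors(n=8):
    return hnp.arrays(np.float64, n,
                      elements=st.floats(-100, 100, allow_nan=False)) \
        .filter(lambda v: np.linalg.norm(v) > 1e-6)


class TestCosineDistance:
    def test_identical_maps(self):
        v = np.arange(1.0, 33.0)
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_maps(self):
        v = np.arange(1.0, 33.0)
        assert cosine_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_maps(self):
        assert cosine_distance(np.array([1.0, 0.0]),
                               np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_scale_invariance_example(self):
        v = np.array([2.0, -1.0, 3.0])
        assert cosine_distance(v, 3.0 * v) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance(np.zeros(4), np.ones(4))

    @settings(deadline=None, max_examples=50)
    @given(u=_nonzero_vectors(), v=_nonzero_vectors(),
           s=st.floats(0.1, 50.0))
    def test_symmetry_range_scale_properties(self, u, v, s):
        d = cosine_distance(u, v)
        assert -1e-9 <= d <= 2.0 + 1e-9
        assert d == pytest.approx(cosine_distance(v, u), abs=1e-9)
        assert cosine_distance(s * u, v) == pytest.approx(d, abs=1e-7)
        assert cosine_distance(u, u) == pytest.approx(0.0, abs=1e-9)
        assert cosine_distance(u, -u) == pytest.approx(2.0, abs=1e-9)


def _exhaustive_p(subj_erps, cond_a, cond_b, window, window_ms):
    """Enumerate all 2^n within-subject label swaps (the identity included)."""
    lo, hi = window
    A, B = [], []
    for erp in subj_erps:
        t = erp.time_ms
        mask = (t >= lo) & (t < hi)
        A.append(erp.erps[cond_a][:, mask].mean(axis=1))
        B.append(erp.erps[cond_b][:, mask].mean(axis=1))
    A, B = np.stack(A), np.stack(B)
    d_obs = cosine_distance(A.mean(0), B.mean(0))
    n = A.shape[0]
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        s = np.array(signs, dtype=bool)
        ga = np.where(s[:, None], B, A).mean(0)
        gb = np.where(s[:, None], A, B).mean(0)
        count += cosine_distance(ga, gb) >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


class TestTanovaWindow:
    def test_identical_conditions_give_p_one(self, montage8):
        erps = make_subject_erps(5, montage8, seed=1)
        for e in erps:
            e.erps["B"] = e.erps["A"].copy()
        d, p = tanova_window(erps, "A", "B", (0.0, 10.0),
                            TanovaConfig(n_shuffles=99, seed=0))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_monte_carlo_matches_exhaustive_n6(self, montage8):
        erps = make_subject_erps(6, montage8, seed=7, noise_sd=1.0,
                                 pattern=np.arange(8) - 3.5,
                                 pattern_window_ms=(0.0, 50.0),
                                 pattern_amp=1.0)
        window = (0.0, 50.0)
        d_obs, p_exh = _exhaustive_p(erps, "A", "B", window, 50.0)
        cfg = TanovaConfig(window_ms=50.0, n_shuffles=5000, seed=11)
        d_mc, p_mc = tanova_window(erps, "A", "B", window, cfg)
        assert d_mc == pytest.approx(d_obs, abs=1e-12)
        se = np.sqrt(p_exh * (1 - p_exh) / 5000)
        assert abs(p_mc - p_exh) < max(0.02, 3 * se)

    def test_planted_difference_reaches_minimum_p(self, montage32):
        rng = np.random.default_rng(2)
        pattern = rng.standard_normal(32)
        erps = make_subject_erps(16, montage32, seed=3, noise_sd=0.05,
                                 pattern=pattern,
                                 pattern_window_ms=(0.0, 600.0),
                                 pattern_amp=5.0)
        cfg = TanovaConfig(window_ms=50.0, n_shuffles=199, seed=5)
        _, p = tanova_window(erps, "A", "B", (100.0, 150.0), cfg)
        assert p == pytest.approx(1.0 / 200.0)

    def test_missing_condition_rejected(self, montage8):
        erps = make_subject_erps(3, montage8)
        del erps[1].erps["B"]
        with pytest.raises(ValueError, match="missing"):
            tanova_window(erps, "A", "B", (0.0, 10.0),
                          TanovaConfig(n_shuffles=9))


class TestTanovaSeries:
    def test_identical_conditions_no_window_below_threshold(self, montage8):
        erps = make_subject_erps(5, montage8, seed=4)
        for e in erps:
            e.erps["B"] = e.erps["A"].copy()
        cfg = TanovaConfig(n_shuffles=99, seed=0)
        res = tanova_series(erps, "A", "B", (0.0, 100.0), cfg)
        assert np.all(res.p == 1.0)
        corrected = cluster_correct(res, cfg)
        assert corrected.clusters == []

    def test_tiling_arithmetic(self, montage8):
        erps = make_subject_erps(3, montage8, seed=5)
        res = tanova_series(erps, "A", "B", (0.0, 100.0),
                            TanovaConfig(n_shuffles=9, seed=0))
        assert res.n_windows == 10
        np.testing.assert_allclose(res.window_starts_ms,
                                   np.arange(0, 100, 10.0))

    def test_nontiling_range_rejected(self, montage8):
        erps = make_subject_erps(3, montage8)
        with pytest.raises(ValueError, match="tile"):
            tanova_series(erps, "A", "B", (0.0, 95.0),
                          TanovaConfig(n_shuffles=9))

    def test_effect_localized_to_planted_window(self, montage32):
        rng = np.random.default_rng(6)
        erps = make_subject_erps(16, montage32, seed=6, noise_sd=0.3,
                                 pattern=rng.standard_normal(32),
                                 pattern_window_ms=(150.0, 250.0),
                                 pattern_amp=4.0)
        cfg = TanovaConfig(n_shuffles=199, seed=7)
        res = tanova_series(erps, "A", "B", (0.0, 600.0), cfg)
        # every planted window is suprathreshold ...
        planted = (res.window_starts_ms >= 150.0) \
            & (res.window_starts_ms < 250.0)
        assert np.all(res.p[planted] < cfg.precluster_p)
        # ... and the dominant corrected cluster sits on the planted interval
        corrected = cluster_correct(res, cfg)
        top = max(corrected.clusters, key=lambda c: c.mass)
        assert top.significant
        assert 140.0 <= top.start_ms <= 160.0
        assert 240.0 <= top.end_ms <= 260.0

    def test_null_window_p_roughly_uniform(self, montage8):
        ps = []
        for r in range(20):
            erps = make_subject_erps(8, montage8, seed=300 + r)
            res = tanova_series(erps, "A", "B", (0.0, 200.0),
                                TanovaConfig(n_shuffles=99, seed=400 + r))
            ps.append(res.p)
        ps = np.concatenate(ps)
        assert abs(ps.mean() - 0.5) < 0.06
        assert abs((ps < 0.25).mean() - 0.25) < 0.08


class TestClusterCorrect:
    def test_requires_stored_shuffles(self, montage8):
        erps = make_subject_erps(3, montage8)
        res = tanova_series(erps, "A", "B", (0.0, 100.0),
                            TanovaConfig(n_shuffles=9, seed=0))
        res.d_null = None
        with pytest.raises(ValueError, match="recompute"):
            cluster_correct(res)

    def test_planted_cluster_recovered_and_onset_within_one_window(
            self, montage32):
        rng = np.random.default_rng(8)
        erps = make_subject_erps(16, montage32, seed=8, noise_sd=0.3,
                                 pattern=rng.standard_normal(32),
                                 pattern_window_ms=(200.0, 300.0),
                                 pattern_amp=4.0)
        cfg = TanovaConfig(n_shuffles=199, seed=9)
        res = cluster_correct(tanova_series(erps, "A", "B", (0.0, 600.0),
                                            cfg), cfg)
        sig = [c for c in res.clusters if c.significant]
        assert sig
        onset = res.earliest_significant_onset_ms()
        assert abs(onset - 200.0) <= 10.0

    def test_cluster_fields_consistent(self, montage32):
        rng = np.random.default_rng(10)
        erps = make_subject_erps(12, montage32, seed=10, noise_sd=0.5,
                                 pattern=rng.standard_normal(32),
                                 pattern_window_ms=(100.0, 400.0),
                                 pattern_amp=3.0)
        cfg = TanovaConfig(n_shuffles=99, seed=11)
        res = cluster_correct(tanova_series(erps, "A", "B", (0.0, 600.0),
                                            cfg), cfg)
        for c in res.clusters:
            assert c.end_ms > c.start_ms
            assert c.mass > 0
            assert 1.0 / 100.0 <= c.p_corrected <= 1.0


class TestPooledComparison:
    def test_pool_of_one_reduces_to_pairwise(self, montage8):
        erps = make_subject_erps(6, montage8, seed=12, noise_sd=1.0)
        cfg = TanovaConfig(n_shuffles=99, seed=13)
        pooled = pooled_comparison(erps, "A", ["B"], (0.0, 100.0), cfg)
        pair = cluster_correct(tanova_series(erps, "A", "B", (0.0, 100.0),
                                             cfg), cfg)
        np.testing.assert_allclose(pooled.d_obs, pair.d_obs, atol=1e-12)
        np.testing.assert_allclose(pooled.p, pair.p, atol=1e-12)

    def test_identical_members_pool_to_member(self, montage8):
        erps = make_subject_erps(5, montage8, seed=14,
                                 conditions=("X", "B1", "B2", "B3"))
        for e in erps:
            e.erps["B2"] = e.erps["B1"].copy()
            e.erps["B3"] = e.erps["B1"].copy()
        cfg = TanovaConfig(n_shuffles=99, seed=15)
        pooled = pooled_comparison(erps, "X", ["B1", "B2", "B3"],
                                   (0.0, 100.0), cfg)
        pair = cluster_correct(tanova_series(erps, "X", "B1", (0.0, 100.0),
                                             cfg), cfg)
        np.testing.assert_allclose(pooled.d_obs, pair.d_obs, atol=1e-12)

    def test_common_deviation_recovered(self, montage32):
        rng = np.random.default_rng(16)
        pattern = rng.standard_normal(32)
        erps = make_subject_erps(16, montage32, seed=16, noise_sd=0.3,
                                 conditions=("single", "p1", "p2", "p3"))
        t = erps[0].time_ms
        mask = (t >= 100.0) & (t < 300.0)
        for e in erps:
            for c in ("p1", "p2", "p3"):
                e.erps[c][:, mask] += 4.0 * pattern[:, None]
        cfg = TanovaConfig(n_shuffles=199, seed=17)
        res = pooled_comparison(erps, "single", ["p1", "p2", "p3"],
                                (0.0, 600.0), cfg)
        assert any(c.significant for c in res.clusters)

    def test_overlap_rejected(self, montage8):
        erps = make_subject_erps(3, montage8)
        with pytest.raises(ValueError, match="pooled"):
            pooled_comparison(erps, "A", ["A", "B"], (0.0, 100.0),
                              TanovaConfig(n_shuffles=9))
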