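import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulsebeat import (FEATURE_NAMES, InputError, SynthSpec,
                       compute_feature_matrix, generate_video,
                       jonckheere_stat, preprocess_sequence, sample_pixels)
from pulsebeat.features import (PixelSample, chi_square_hist,
                                compute_feature_row, friedman_chi_square,
                                kruskal_wallis, ks_statistic, mann_whitney_u,
                                pearson_correlation, regression_slope, rmse,
                                wilcoxon_signed_rank)
from pulsebeat.preprocess import PreprocessConfig


def _samples(arrays):
    pos = np.zeros((len(arrays[0]), 2), dtype=int)
    return [PixelSample(values=np.asarray(a, float), frame_index=i,
                        positions=pos) for i, a in enumerate(arrays)]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_jonckheere(groups):
    j = 0.0
    for gi in range(len(groups) - 1):
        for hi in range(gi + 1, len(groups)):
            for x in groups[gi]:
                for y in groups[hi]:
                    if x < y:
                        j += 1.0
                    elif x == y:
                        j += 0.5
    return j


def brute_chi_square(x, y, bins=16):
    edges = [255.0 * k / bins for k in range(bins + 1)]
    stat = 0.0
    for k in range(bins):
        lo, hi = edges[k], edges[k + 1]
        if k == bins - 1:
            ox = sum(1 for v in x if lo <= v <= hi)
            oy = sum(1 for v in y if lo <= v <= hi)
        else:
            ox = sum(1 for v in x if lo <= v < hi)
            oy = sum(1 for v in y if lo <= v < hi)
        if ox + oy == 0:
            continue
        e = (ox + oy) / 2.0
        stat += (ox - e) ** 2 / e + (oy - e) ** 2 / e
    return stat


class TestJonckheere:
    @pytest.mark.parametrize("groups,expected", [
        ([[1, 2], [3, 4]], 4.0),      # all 4 cross pairs increasing
        ([[1, 1], [1, 1]], 2.0),      # 4 tied cross pairs × ½
        ([[1], [2], [3]], 3.0),       # 3 increasing pairs
        ([[3, 4], [1, 2]], 0.0),
    ])
    def test_examples(self, groups, expected):
        assert jonckheere_stat(groups) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            jonckheere_stat([[1.0], []])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        k = data.draw(st.integers(2, 4))
        sizes = [data.draw(st.integers(1, 30 // k)) for _ in range(k)]
        groups = [
            [data.draw(st.integers(0, 10)) for _ in range(n)] for n in sizes
        ]
        assert jonckheere_stat(groups) == pytest.approx(
            brute_jonckheere(groups))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_reversal_identity_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.permutation(np.arange(30))[:rng.integers(2, 10)] + 100 * g
                  for g in range(3)]  # distinct values → no ties
        n_pairs = sum(
            len(groups[i]) * len(groups[j])
            for i in range(3) for j in range(i + 1, 3)
        )
        assert jonckheere_stat(groups) + jonckheere_stat(groups[::-1]) \
            == pytest.approx(n_pairs)


class TestStatisticsAgainstReferences:
    """Each authored statistic against an independent implementation."""

    def test_fifty_seeded_windows(self):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n = int(rng.integers(15, 120))
            if trial % 3 == 0:  # integer-valued windows exercise ties
                x, y, z = (rng.integers(0, 40, n).astype(float)
                           for _ in range(3))
            else:
                x, y, z = (rng.normal(120, 30, n) for _ in range(3))
            rel = 1e-8
            assert np.mean(x) == pytest.approx(statistics.fmean(x), rel=rel)
            assert np.median(x) == pytest.approx(
                statistics.median(x.tolist()), rel=rel)
            assert np.var(x, ddof=1) == pytest.approx(
                statistics.variance(x.tolist()), rel=rel)
            assert np.sqrt(np.var(x, ddof=1)) == pytest.approx(
                statistics.stdev(x.tolist()), rel=rel)
            assert pearson_correlation(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, rel=rel)
            assert chi_square_hist(x % 255, y % 255) == pytest.approx(
                brute_chi_square(x % 255, y % 255), rel=rel)
            assert rmse(x, y) == pytest.approx(
                float(np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / n)),
                rel=rel)
            assert regression_slope(y, x) == pytest.approx(
                stats.linregress(y, x).slope, rel=rel)
            if np.any(x != y):
                assert wilcoxon_signed_rank(x, y) == pytest.approx(
                    stats.wilcoxon(x, y, alternative="greater").statistic,
                    rel=rel)
            assert mann_whitney_u(x, y) == pytest.approx(
                stats.mannwhitneyu(x, y).statistic, rel=rel)
            assert ks_statistic(x, y) == pytest.approx(
                stats.ks_2samp(x, y).statistic, rel=rel)
            if np.ptp(np.concatenate([x, y, z])) > 0:
                assert kruskal_wallis([z, y, x]) == pytest.approx(
                    stats.kruskal(z, y, x).statistic, rel=rel)
            fried_ref = stats.friedmanchisquare(z, y, x).statistic
            if np.isfinite(fried_ref):
                assert friedman_chi_square([z, y, x]) == pytest.approx(
                    fried_ref, rel=rel)

    def test_mann_whitney_swap_identity(self, rng):
        x = rng.integers(0, 50, 80).astype(float)
        y = rng.integers(0, 50, 60).astype(float)
        assert mann_whitney_u(x, y) + mann_whitney_u(y, x) \
            == pytest.approx(80 * 60)


class TestFeatureRow:
    def test_identical_samples_degeneracies(self):
        a = np.full(64, 50.0)
        row = dict(zip(FEATURE_NAMES, compute_feature_row(a, a, a)))
        for name in ("ks", "rmse", "chi_square", "kruskal_wallis",
                     "friedman", "correlation", "wilcoxon"):
            assert row[name] == 0.0

    def test_exact_linear_relation(self):
        prev = np.array([1.0, 2, 3, 4])
        cur = np.array([2.0, 4, 6, 8])
        row = dict(zip(FEATURE_NAMES,
                       compute_feature_row(prev, prev, cur)))
        assert row["regression_slope"] == pytest.approx(2.0)
        assert row["correlation"] == pytest.approx(1.0)

    def test_disjoint_samples_give_ks_one(self):
        assert ks_statistic(np.array([1.0, 1.0]),
                            np.array([0.0, 0.0])) == 1.0

    def test_variance_std_consistency_and_finiteness(self, short_video,
                                                     small_config):
        processed = preprocess_sequence(short_video, small_config)
        samples = sample_pixels(processed, max_pixels=512, seed=7)
        matrix = compute_feature_matrix(samples, processed.timestamps)
        assert np.all(np.isfinite(matrix.values))
        np.testing.assert_allclose(matrix.column("variance"),
                                   matrix.column("std") ** 2, rtol=1e-9)
        assert np.all((matrix.column("ks") >= 0) & (matrix.column("ks") <= 1))
        for name in ("chi_square", "rmse", "kruskal_wallis", "friedman"):
            assert np.all(matrix.column(name) >= 0)
        # window warm-up: first row is frame index 2
        assert matrix.frame_indices[0] == 2
        assert matrix.values.shape == (short_video.n_frames - 2,
                                       len(FEATURE_NAMES))

    def test_fewer_than_three_frames_rejected(self):
        s = _samples([[1, 2], [3, 4]])
        with pytest.raises(InputError):
            compute_feature_matrix(s, np.array([0.0, 0.1]))


class TestSamplePixels:
    def test_small_frames_enumerate_row_major(self, small_config):
        spec_video = generate_video(
            SynthSpec(bpm=72, fps=30, duration=0.2, frame_size=32, seed=1))
        processed = preprocess_sequence(
            spec_video, PreprocessConfig(target_size=32))
        samples = sample_pixels(processed, max_pixels=2048, seed=7)
        assert len(samples[0].values) == 32 * 32
        expected = np.column_stack(
            np.unravel_index(np.arange(32 * 32), (32, 32)))
        assert np.array_equal(samples[0].positions, expected)

    def test_positions_shared_and_deterministic(self, short_video,
                                                small_config):
        processed = preprocess_sequence(short_video, small_config)
        a = sample_pixels(processed, max_pixels=256, seed=7)
        b = sample_pixels(processed, max_pixels=256, seed=7)
        assert np.array_equal(a[0].positions, b[0].positions)
        assert all(np.array_equal(s.positions, a[0].positions) for s in a)
        assert len(a[0].values) == 256
        c = sample_pixels(processed, max_pixels=256, seed=8)
        assert not np.array_equal(a[0].positions, c[0].positions)
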