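"""Copy-number pipeline: normalization oracles, segmentation, merging,
deletion calls, and critical-region interval arithmetic."""

import numpy as np
import pytest

from episig.cnv import (
    CnvSegment,
    GenomicInterval,
    call_deletions,
    critical_region,
    interval_length_mb,
    log_ratio,
    merge_segments,
    phmds_deletion_intervals,
    quantile_normalize,
    reciprocal_overlap,
    segment,
    total_intensity,
)


class TestTotalIntensity:
    def test_elementwise_sum(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(size=(5, 4)), rng.uniform(size=(5, 4))
        assert np.allclose(total_intensity(a, b), a + b)
        assert total_intensity(np.array(3.0), np.array(4.0)) == 7.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_intensity(np.zeros((2, 2)), np.zeros((3, 2)))


def _qn_oracle(X):
    """sort / cross-column mean / unsort (valid when columns have no ties)."""
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[np.argsort(X[:, j], kind="mergesort"), j] = target
    return out


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        X = np.column_stack([col, col, col])
        assert np.allclose(quantile_normalize(X), X)

    def test_columns_share_distribution_afterward(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(size=(50, 4)) * [1, 2, 5, 10]
        out = quantile_normalize(X)
        sorted_cols = np.sort(out, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, :1])

    def test_matches_sort_mean_unsort_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 3))
        assert np.allclose(quantile_normalize(X), _qn_oracle(X), atol=1e-12)

    def test_ties_get_average_of_targets(self):
        X = np.array([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]])
        out = quantile_normalize(X)
        # tied pair in column 0 shares the mean of the two lowest targets
        assert out[0, 0] == out[1, 0] == pytest.approx((out[:, 1].min() + np.sort(out[:, 1])[1]) / 2)


class TestLogRatio:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (0.5, -0.30103), (2.0, 0.30103)])
    def test_reference_points(self, ratio, expected):
        r = log_ratio(np.array([ratio * 100.0]), np.array([100.0]))
        assert r[0] == pytest.approx(expected, abs=1e-5)

    def test_zero_median_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="median"):
            r = log_ratio(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert np.isnan(r[0]) and r[1] == pytest.approx(np.log10(2))


def _oracle_best_arc(x):
    """Exhaustive scan of every arc [i, j): maximal standardized
    |mean(arc) - mean(rest)|."""
    n = x.size
    s = x.std(ddof=1)
    best = (0, n, 0.0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            w = j - i
            if w == n:
                continue
            m_in = x[i:j].mean()
            m_out = (x.sum() - x[i:j].sum()) / (n - w)
            T = abs(m_in - m_out) / (s * np.sqrt(1 / w + 1 / (n - w)))
            if T > best[2]:
                best = (i, j, T)
    return best


class TestSegment:
    def test_noiseless_step_recovered_at_exact_breakpoint(self):
        pos = np.arange(200) * 1000 + 1
        r = np.concatenate([np.zeros(100), np.full(100, -0.3)])
        i, j, _ = _oracle_best_arc(r)
        assert {i, j} & {100}  # oracle puts a boundary between probes 100/101
        segs = merge_segments(segment(r, pos, n_perm=500, seed=1))
        assert len(segs) == 2
        assert segs[0].end == pos[99] and segs[1].start == pos[100]
        assert segs[0].mean_log_ratio == pytest.approx(0.0)
        assert segs[1].mean_log_ratio == pytest.approx(-0.3)

    def test_pure_noise_stays_single_segment(self):
        pos = np.arange(200) * 1000 + 1
        single = 0
        for s in range(20):
            r = np.random.default_rng(s).normal(0, 0.05, 200)
            single += len(segment(r, pos, n_perm=500, seed=1)) == 1
        assert single >= 19

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        r = rng.normal(0, 0.05, 300)
        r[100:150] -= 0.3
        pos = np.arange(300) * 1000 + 1
        a = segment(r, pos, n_perm=500, seed=7)
        b = segment(r, pos, n_perm=500, seed=7)
        assert [(s.start, s.end, s.mean_log_ratio) for s in a] == [
            (s.start, s.end, s.mean_log_ratio) for s in b
        ]

    def test_partition_and_rss_improvement(self):
        rng = np.random.default_rng(4)
        r = rng.normal(0, 0.05, 400)
        r[150:250] -= 0.3
        pos = np.arange(400) * 1000 + 1
        segs = segment(r, pos, n_perm=500, seed=2)
        assert sum(s.n_probes for s in segs) == 400
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start
        fit = np.concatenate([np.full(s.n_probes, s.mean_log_ratio) for s in segs])
        rss_seg = np.sum((r - fit) ** 2)
        rss_one = np.sum((r - r.mean()) ** 2)
        assert rss_seg <= rss_one

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            segment(np.zeros(10), np.arange(10) * 100 + 1, n_perm=10)


class TestMergeSegments:
    def test_close_means_merged_weighted(self):
        segs = [
            CnvSegment("chr1", 1, 100, 10, -0.28),
            CnvSegment("chr1", 101, 200, 30, -0.25),
        ]
        out = merge_segments(segs)
        assert len(out) == 1
        assert out[0].mean_log_ratio == pytest.approx((-0.28 * 10 - 0.25 * 30) / 40)
        assert (out[0].start, out[0].end, out[0].n_probes) == (1, 200, 40)

    def test_distant_means_kept_separate(self):
        segs = [
            CnvSegment("chr1", 1, 100, 10, 0.0),
            CnvSegment("chr1", 101, 200, 10, -0.30),
        ]
        assert len(merge_segments(segs)) == 2

    def test_single_segment_unchanged(self):
        segs = [CnvSegment("chr1", 1, 100, 10, -0.2)]
        assert merge_segments(segs) == segs


class TestCallDeletions:
    def test_neutral_and_gain_not_called(self):
        segs = [
            CnvSegment("chr1", 1, 100, 50, 0.0),
            CnvSegment("chr1", 101, 200, 50, 0.18),  # ~1.5x gain
        ]
        assert call_deletions(segs) == []

    def test_deletion_called_with_min_probes(self):
        segs = [
            CnvSegment("chr1", 1, 100, 3, -0.3),  # too few probes
            CnvSegment("chr1", 101, 200, 50, -0.3),
        ]
        out = call_deletions(segs, min_probes=5)
        assert [(iv.start, iv.end) for iv in out] == [(101, 200)]


class TestCriticalRegion:
    def test_published_cohort_coordinates_reproduced(self):
        positives, negatives = phmds_deletion_intervals()
        assert len(positives) == 11 and len(negatives) == 5
        region = critical_region(positives, negatives)
        assert len(region) == 1
        assert (region[0].chrom, region[0].start, region[0].end) == (
            "chr22", 49_238_268, 50_248_907,
        )

    def test_no_negatives_is_intersection(self):
        pos = [GenomicInterval("chr1", 10, 100), GenomicInterval("chr1", 50, 120)]
        out = critical_region(pos)
        assert (out[0].start, out[0].end) == (50, 100)

    def test_negatives_covering_intersection_empty(self):
        pos = [GenomicInterval("chr1", 10, 100)]
        neg = [GenomicInterval("chr1", 5, 150)]
        assert critical_region(pos, neg) == []

    def test_disjoint_positives_warn_empty(self):
        pos = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 50, 60)]
        with pytest.warns(UserWarning, match="empty"):
            assert critical_region(pos) == []

    def test_order_invariant_and_idempotent_under_duplicates(self):
        positives, negatives = phmds_deletion_intervals()
        base = critical_region(positives, negatives)
        shuffled = critical_region(positives[::-1], negatives[::-1])
        doubled = critical_region(positives + positives, negatives + negatives)
        assert base == shuffled == doubled

    def test_interior_negative_splits_region(self):
        pos = [GenomicInterval("chr1", 10, 100)]
        neg = [GenomicInterval("chr1", 40, 60)]
        out = critical_region(pos, neg)
        assert [(iv.start, iv.end) for iv in out] == [(10, 40), (60, 100)]


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start,end,decimals,expected",
        [
            (45_250_061, 51_225_561, 2, 5.98),
            (48_651_166, 51_214_353, 2, 2.56),
            (51_135_138, 51_147_735, 3, 0.013),
            (100, 100, 2, 0.0),
        ],
    )
    def test_published_lengths_reproduce(self, start, end, decimals, expected):
        iv = GenomicInterval("chr22", start, end)
        assert interval_length_mb(iv, decimals) == expected

    def test_all_packaged_lengths_match(self):
        from episig.datasets import load_phmds_deletions

        df = load_phmds_deletions()
        for row in df.itertuples():
            decimals = 3 if row.length_mb < 0.1 else 2
            got = interval_length_mb(
                GenomicInterval(row.chrom, row.start, row.end), decimals
            )
            assert got == pytest.approx(row.length_mb, abs=0.011)


class TestEndToEndRecovery:
    def test_planted_deletions_recovered(self, cnv_fixture):
        res = cnv_fixture["results"]
        for sid, truth_iv in cnv_fixture["truth"].items():
            calls = res.deletions[sid]
            best = max((reciprocal_overlap(truth_iv, c) for c in calls), default=0.0)
            assert best >= 0.95, f"{sid}: overlap {best:.3f}"

    def test_mosaic_deletion_below_detection(self, cnv_fixture):
        assert cnv_fixture["results"].deletions[cnv_fixture["mosaic_id"]] == []

    def test_control_chromosome_stays_neutral(self, cnv_fixture):
        res = cnv_fixture["results"]
        for sid in cnv_fixture["truth"]:
            assert all(iv.chrom != "chr21" for iv in res.deletions[sid])
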