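"""GFP, peak detection, spatial correlation, modified K-means (with a
brute-force oracle), GEV, canonical labeling and backfitting."""

import itertools

import numpy as np
import pytest

import eegms
from eegms.microstates import (
    PeakSet,
    TemplateSet,
    _principal_map,
    assign_canonical_labels,
    backfit_labels,
    compute_gev,
    compute_gfp,
    detect_gfp_peaks,
    modified_kmeans,
    spatial_correlation,
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    return v / np.linalg.norm(v)


class TestComputeGFP:
    @pytest.mark.parametrize(
        "frame,expected",
        [
            ([3.0, 3.0, 3.0, 3.0], 0.0),
            ([1.0, -1.0], 1.0),
            ([2.0, 0.0, 1.0, 1.0], np.sqrt(0.5)),
        ],
    )
    def test_hand_cases(self, frame, expected):
        assert compute_gfp(np.array(frame)) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_per_frame(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(19, 50))
        g = compute_gfp(data)
        for i in range(50):
            assert g[i] == pytest.approx(compute_gfp(data[:, i]), abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            compute_gfp(np.array([1.0]))


class TestDetectGFPPeaks:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([0, 1, 0, 2, 0], [1, 3]),
            ([0, 1, 2, 3, 4], []),
            ([1, 1, 1, 1], []),
            ([0, 1, 1, 0], [1]),  # plateau credit to its first sample
        ],
    )
    def test_enumerated_cases(self, series, expected):
        np.testing.assert_array_equal(
            detect_gfp_peaks(np.array(series, dtype=float)), expected
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_gfp_peaks(np.array([1.0, 2.0]))


class TestSpatialCorrelation:
    def test_identity_and_polarity(self):
        v = np.array([1.0, 2.0, -1.0, 0.5])
        assert spatial_correlation(v, v) == pytest.approx(1.0)
        assert spatial_correlation(v, -v) == pytest.approx(1.0)
        assert spatial_correlation(v, -v, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(5), np.arange(5.0))


def brute_force_best_gev(peaks: PeakSet, k: int) -> float:
    """Oracle: exhaustive enumeration of all assignments, each scored with
    the eigenvector template update, maximizing GEV."""
    best = 0.0
    n = peaks.n_peaks
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        if np.unique(assign).size < k:
            continue
        templates = np.vstack([
            _principal_map(peaks.maps[assign == j]) for j in range(k)
        ])
        best = max(best, compute_gev(peaks, assign, templates))
    return best


def _random_peaks(rng, n_peaks, n_ch=8):
    maps = rng.normal(size=(n_peaks, n_ch))
    return PeakSet(
        indices=np.arange(n_peaks), maps=maps,
        gfp=compute_gfp(maps.T),
    )


class TestModifiedKmeans:
    def test_two_orthogonal_clusters_recovered(self):
        t1 = _unit([1, -1, 0, 0, 0, 0])
        t2 = _unit([0, 0, 1, -1, 0, 0])
        maps = np.vstack([t1, -t1, t1, t2, -t2, t2]) * 2.0
        peaks = PeakSet(indices=np.arange(6), maps=maps, gfp=np.full(6, 1.0))
        ts, assign = modified_kmeans(peaks, k=2, n_restarts=5, seed=0)
        assert ts.gev == pytest.approx(1.0, abs=1e-12)
        rs = sorted(
            max(spatial_correlation(m, t1), spatial_correlation(m, t2))
            for m in ts.maps
        )
        assert rs[0] == pytest.approx(1.0, abs=1e-9)
        # the two template estimates span both targets
        assert spatial_correlation(ts.maps[0], ts.maps[1]) < 0.5

    def test_k_equals_n_peaks_gives_gev_one(self):
        rng = np.random.default_rng(1)
        peaks = _random_peaks(rng, 4)
        ts, _ = modified_kmeans(peaks, k=4, n_restarts=10, seed=0)
        assert ts.gev == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_tiny_instances(self, seed):
        """Best-of-restarts GEV equals the exhaustive-assignment optimum
        on <= 8 peaks with K = 2."""
        rng = np.random.default_rng(seed)
        peaks = _random_peaks(rng, int(rng.integers(5, 9)))
        ts, _ = modified_kmeans(peaks, k=2, n_restarts=200, seed=seed)
        oracle = brute_force_best_gev(peaks, 2)
        assert ts.gev == pytest.approx(oracle, abs=1e-9)

    def test_polarity_flip_invariance(self):
        rng = np.random.default_rng(3)
        peaks = _random_peaks(rng, 30, n_ch=10)
        flipped_maps = peaks.maps.copy()
        flip = rng.random(30) < 0.5
        flipped_maps[flip] *= -1
        flipped = PeakSet(indices=peaks.indices, maps=flipped_maps, gfp=peaks.gfp)
        ts1, a1 = modified_kmeans(peaks, k=3, n_restarts=10, seed=7)
        ts2, a2 = modified_kmeans(flipped, k=3, n_restarts=10, seed=7)
        assert ts1.gev == pytest.approx(ts2.gev, abs=1e-12)
        for m1, m2 in zip(ts1.maps, ts2.maps):
            assert spatial_correlation(m1, m2) == pytest.approx(1.0, abs=1e-9)

    def test_gev_nondecreasing_in_k(self, templates):
        rng = np.random.default_rng(4)
        idx = rng.integers(0, 4, size=120)
        maps = templates[idx] * rng.uniform(1, 3, (120, 1))
        maps += rng.normal(0, 0.05, maps.shape)
        peaks = PeakSet(
            indices=np.arange(120), maps=maps, gfp=compute_gfp(maps.T)
        )
        gevs = [
            modified_kmeans(peaks, k=k, n_restarts=10, seed=0)[0].gev
            for k in range(2, 7)
        ]
        assert np.all(np.diff(gevs) >= -1e-9)

    def test_too_few_peaks_rejected(self):
        peaks = _random_peaks(np.random.default_rng(5), 3)
        with pytest.raises(ValueError):
            modified_kmeans(peaks, k=4)


class TestComputeGEV:
    def test_collinear_is_one_orthogonal_is_zero(self):
        t1 = _unit([1, -1, 0, 0])
        t_perp = _unit([0, 0, 1, -1])
        peaks = PeakSet(
            indices=[0, 1], maps=np.vstack([t1, 2 * t1]), gfp=[1.0, 2.0]
        )
        assert compute_gev(peaks, [0, 0], t1[None]) == pytest.approx(1.0)
        assert compute_gev(peaks, [0, 0], t_perp[None]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        """GFP = (1, 2), r = (1, 0.5) -> (1 + 1)/(1 + 4) = 0.4."""
        t1 = _unit([1, -1, 0, 0])
        t_perp = _unit([0, 0, 1, -1])
        m2 = 0.5 * t1 + np.sqrt(0.75) * t_perp
        peaks = PeakSet(indices=[0, 1], maps=np.vstack([t1, m2]), gfp=[1.0, 2.0])
        assert compute_gev(peaks, [0, 0], t1[None]) == pytest.approx(0.4, abs=1e-12)


class TestCanonicalLabels:
    def test_identity_swap_and_negation(self, templates):
        ts = TemplateSet(maps=templates.copy())
        out = assign_canonical_labels(ts, templates)
        assert out.labels == ("A", "B", "C", "D")
        np.testing.assert_allclose(out.maps, templates, atol=1e-12)

        swapped = TemplateSet(maps=templates[[1, 0, 2, 3]])
        out = assign_canonical_labels(swapped, templates)
        np.testing.assert_allclose(out.maps, templates, atol=1e-12)

        neg = TemplateSet(maps=-templates)
        out = assign_canonical_labels(neg, templates)
        np.testing.assert_allclose(np.abs(out.maps), np.abs(templates), atol=1e-12)

    def test_montage_mismatch_rejected(self, templates):
        ts = TemplateSet(maps=templates)
        with pytest.raises(ValueError):
            assign_canonical_labels(ts, templates[:, :10])


class TestBackfitLabels:
    def _two_peak_epoch(self, templates, n=30):
        env = 0.5 - 0.01 * np.arange(n)  # strictly decreasing baseline
        env[10], env[20] = 2.0, 1.5
        maps = np.where(np.arange(n)[None, :] < 15, templates[0][:, None],
                        templates[1][:, None])
        return maps * env

    def test_midpoint_rule(self, templates):
        ts = TemplateSet(maps=templates, labels=("A", "B", "C", "D"))
        seg = backfit_labels(self._two_peak_epoch(templates), ts)
        np.testing.assert_array_equal(seg.peak_indices, [10, 20])
        assert np.all(seg.sample_labels[:16] == 0)  # midpoint 15 stays A
        assert np.all(seg.sample_labels[16:] == 1)

    def test_single_peak_labels_whole_epoch(self, templates):
        ts = TemplateSet(maps=templates, labels=("A", "B", "C", "D"))
        env = np.full(20, 0.1)
        env[7] = 3.0
        epoch = templates[2][:, None] * env
        seg = backfit_labels(epoch, ts)
        assert np.all(seg.sample_labels == 2)

    def test_noiseless_epoch_matches_ground_truth(self, templates):
        groups = {
            g: eegms.GroupParams(
                p.occurrence_weight, p.mean_duration_ms, p.gfp_scale,
                p.duration_shape, noise_sd=0.0,
            )
            for g, p in eegms.GeneratorConfig().groups.items()
        }
        cfg = eegms.GeneratorConfig(n_per_group=1, duration=10.0, seed=2, groups=groups)
        seq = eegms.sample_state_sequence(cfg, "HC", seed=4)
        rec, gt = eegms.synthesize_recording(seq, templates, cfg, "HC", seed=4)
        ts = TemplateSet(maps=templates, labels=("A", "B", "C", "D"))
        seg = backfit_labels(rec.data, ts)
        agree = np.mean(seg.sample_labels == gt.state_sequence)
        assert agree >= 0.95

    def test_no_peaks_rejected(self, templates):
        ts = TemplateSet(maps=templates)
        with pytest.raises(ValueError):
            backfit_labels(np.zeros((19, 50)), ts)
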