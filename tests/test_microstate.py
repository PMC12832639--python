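import itertools

import numpy as np
import pytest

import eegrisk as er
from eegrisk import microstate as ms
from eegrisk.synth import LabelSequence, MicrostateTemplates


class TestGFP:
    def test_constant_sample_zero(self, montage):
        rec = er.EEGRecording(data=np.full((19, 10), 2.5), fs=10.0,
                              montage=montage)
        np.testing.assert_allclose(ms.gfp(rec).values, 0.0, atol=1e-12)

    def test_two_channel_antisymmetric(self):
        from eegrisk.montage import Montage
        m = Montage(channel_names=("a", "b"), positions=np.eye(3)[:2])
        rec = er.EEGRecording(data=np.array([[1.0], [-1.0]]), fs=1.0,
                              montage=m)
        assert ms.gfp(rec).values[0] == pytest.approx(1.0)

    def test_homogeneous_scaling(self, planted_recording):
        rec, _ = planted_recording
        scaled = rec.copy_with(rec.data * 3.0)
        np.testing.assert_allclose(
            ms.gfp(scaled).values, 3.0 * ms.gfp(rec).values, rtol=1e-12)


class TestPeakFinding:
    def test_monotone_series_has_no_peaks(self):
        series = ms.GFPSeries(values=np.linspace(0, 1, 500), fs=500.0)
        assert ms.find_gfp_peaks(series).size == 0

    def test_sinusoidal_gfp_peak_rate_and_spacing(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        series = ms.GFPSeries(values=1.0 + 0.5 * np.sin(2 * np.pi * 5 * t),
                              fs=fs)
        idx = ms.find_gfp_peaks(series)
        # one peak per 200 ms period
        assert abs(idx.size - 50) <= 1
        assert np.diff(idx).min() >= int(0.010 * fs)

    def test_outlier_peak_excluded(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        values = 1.0 + 0.1 * np.sin(2 * np.pi * 5 * t)
        spike = 10_000
        values[spike] = values.mean() + 5 * values.std()
        series = ms.GFPSeries(values=values, fs=fs)
        assert spike not in ms.find_gfp_peaks(series)

    def test_constant_series_yields_empty_set(self):
        series = ms.GFPSeries(values=np.ones(1000), fs=100.0)
        assert ms.find_gfp_peaks(series).size == 0


def _orthogonal_peakset(n_per_class=6, seed=0):
    """Peak maps drawn exactly from 4 mutually orthogonal topographies."""
    rng = np.random.default_rng(seed)
    base = np.linalg.qr(rng.normal(size=(8, 8)))[0][:4]
    base = base - base.mean(axis=1, keepdims=True)
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    labels = np.repeat(np.arange(4), n_per_class)
    amps = rng.uniform(0.5, 2.0, labels.size)
    maps = base[labels] * amps[:, None]
    peaks = ms.PeakSet(indices=np.arange(labels.size), maps=maps)
    return peaks, base, labels


class TestModifiedKMeans:
    def test_perfect_fit_limit(self):
        peaks, base, labels = _orthogonal_peakset()
        seg = ms.modified_kmeans(peaks, MicrostateTemplates(maps=base))
        assert seg.gev == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(seg.peak_labels, labels)
        assert seg.gev_per_class.sum() == pytest.approx(seg.gev, abs=1e-12)

    def test_polarity_invariance(self):
        peaks, base, _ = _orthogonal_peakset(seed=2)
        flipped = peaks.maps.copy()
        flipped[1::2] *= -1
        seg_a = ms.modified_kmeans(peaks, MicrostateTemplates(maps=base))
        seg_b = ms.modified_kmeans(
            ms.PeakSet(indices=peaks.indices, maps=flipped),
            MicrostateTemplates(maps=base))
        assert np.array_equal(seg_a.peak_labels, seg_b.peak_labels)
        assert seg_a.gev == pytest.approx(seg_b.gev, abs=1e-12)

    def test_gev_trace_non_decreasing(self, planted_recording, templates):
        rec, _ = planted_recording
        noisy = rec.copy_with(
            rec.data + 0.1 * np.random.default_rng(6).normal(
                size=rec.data.shape))
        peaks = ms.extract_peaks(noisy)
        seg = ms.modified_kmeans(peaks, templates)
        assert np.all(np.diff(seg.gev_trace) >= -1e-12)

    def test_too_few_peaks_rejected(self, templates):
        peaks = ms.PeakSet(indices=np.arange(3),
                           maps=np.random.default_rng(0).normal(size=(3, 19)))
        with pytest.raises(ValueError):
            ms.modified_kmeans(peaks, templates)

    def test_matches_exhaustive_gev_oracle_on_toy(self):
        """K=2, 8 peaks, 3 channels: compare with brute force over all
        2^8 assignments, each scored with its optimal (dominant
        eigenvector) templates."""
        rng = np.random.default_rng(8)
        t1 = np.array([1.0, -0.5, -0.5])
        t2 = np.array([-0.4, 0.9, -0.5])
        signs = rng.choice([-1.0, 1.0], 8)
        labels_true = np.repeat([0, 1], 4)
        maps = np.array([(t1 if l == 0 else t2) * s
                         for l, s in zip(labels_true, signs)])
        maps += 0.05 * rng.normal(size=maps.shape)
        maps = maps - maps.mean(axis=1, keepdims=True)
        peaks = ms.PeakSet(indices=np.arange(8), maps=maps)

        gfp2 = maps.var(axis=1, ddof=0)
        denom = gfp2.sum()

        def assignment_gev(assign):
            total = 0.0
            for k in (0, 1):
                members = maps[np.array(assign) == k]
                if members.shape[0] == 0:
                    continue
                w, vecs = np.linalg.eigh(members.T @ members)
                t = vecs[:, -1]
                t = t - t.mean()
                t /= np.linalg.norm(t)
                corr = ms.spatial_correlation(members, t)[:, 0]
                total += np.sum(corr ** 2
                                * members.var(axis=1, ddof=0))
            return total / denom

        best_oracle = max(
            assignment_gev(a)
            for a in itertools.product((0, 1), repeat=8))

        init = MicrostateTemplates(
            maps=np.vstack([t1 - t1.mean(), t2 - t2.mean()]),
            class_ids=("A", "B"))
        seg = ms.modified_kmeans(peaks, init)
        assert seg.gev == pytest.approx(best_oracle, abs=1e-9)


class TestTemplateSearch:
    def _toy_peaks(self, templates, n=20, seed=3):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, n)
        amps = rng.uniform(0.5, 2.0, n)
        maps = templates.maps[labels] * amps[:, None] \
            + 0.05 * rng.normal(size=(n, 19))
        return ms.PeakSet(indices=np.arange(n), maps=maps)

    def test_candidate_counts_give_630_initializations(self, montage,
                                                       templates):
        bank = er.candidate_template_bank(montage, (7, 5, 6, 3))
        assert [len(b) for b in bank] == [7, 5, 6, 3]
        peaks = self._toy_peaks(templates)
        seg = ms.search_template_combinations(peaks, bank)
        assert seg.n_initializations == 630

    def test_single_candidate_equals_single_run(self, montage, templates):
        bank = er.candidate_template_bank(montage, (1, 1, 1, 1))
        peaks = self._toy_peaks(templates, seed=4)
        searched = ms.search_template_combinations(peaks, bank)
        direct = ms.modified_kmeans(
            peaks, MicrostateTemplates(maps=np.vstack([b[0] for b in bank])))
        assert searched.n_initializations == 1
        assert searched.gev == pytest.approx(direct.gev, abs=1e-12)

    def test_search_returns_maximum_over_individual_runs(self, montage,
                                                         templates):
        bank = er.candidate_template_bank(montage, (2, 2, 2, 2))
        peaks = self._toy_peaks(templates, seed=5)
        best = ms.search_template_combinations(peaks, bank)
        for combo in itertools.product(range(2), repeat=4):
            init = MicrostateTemplates(maps=np.vstack(
                [bank[c][i] for c, i in enumerate(combo)]))
            run = ms.modified_kmeans(peaks, init)
            assert best.gev >= run.gev - 1e-12


class TestBackfit:
    def test_noise_free_recovery_is_exact(self, planted_recording,
                                          templates):
        rec, seq = planted_recording
        labels = ms.backfit(rec, templates)
        assert labels.n_samples == rec.n_samples
        assert np.array_equal(labels.labels, seq.labels)

    def test_sign_flip_invariance(self, planted_recording, templates):
        rec, _ = planted_recording
        flipped = rec.copy_with(-rec.data)
        np.testing.assert_array_equal(
            ms.backfit(rec, templates).labels,
            ms.backfit(flipped, templates).labels)


class TestSegmentFilter:
    def test_compliant_runs_untouched(self):
        fs = 500.0
        labels = np.repeat([0, 1, 2, 3], 25)          # 50 ms runs
        seq = LabelSequence(labels=labels, fs=fs)
        out = ms.filter_segments(seq)
        np.testing.assert_array_equal(out.labels, labels)

    def test_short_run_unassigned(self):
        fs = 500.0
        labels = np.concatenate([np.full(25, 0), np.full(2, 1),
                                 np.full(25, 2)])     # 4 ms run of B
        out = ms.filter_segments(LabelSequence(labels=labels, fs=fs))
        assert np.all(out.labels[25:27] == ms.UNASSIGNED)
        assert np.all(out.labels[:25] == 0)
        assert np.all(out.labels[27:] == 2)

    def test_long_run_unassigned_neighbours_stay_separate(self):
        fs = 500.0
        labels = np.concatenate([np.full(25, 0), np.full(100, 1),
                                 np.full(25, 0)])     # 200 ms run of B
        out = ms.filter_segments(LabelSequence(labels=labels, fs=fs))
        assert np.all(out.labels[25:125] == ms.UNASSIGNED)
        stats = ms.microstate_statistics(out)
        assert stats.mfo_hz["A"] * (150 / fs) == pytest.approx(2.0)


class TestStatistics:
    def test_full_coverage_single_class(self):
        fs = 500.0
        seq = LabelSequence(labels=np.zeros(int(60 * fs), dtype=int), fs=fs)
        stats = ms.microstate_statistics(seq)
        assert stats.mc_pct["A"] == pytest.approx(100.0)
        assert stats.mfo_hz["A"] == pytest.approx(1.0 / 60.0)
        assert stats.mmd_ms["A"] == pytest.approx(60_000.0)

    def test_hand_counted_example(self):
        fs = 1000.0
        labels = np.concatenate([np.full(50, 0), np.full(50, 1),
                                 np.full(30, 0), np.full(70, 1)])
        stats = ms.microstate_statistics(LabelSequence(labels=labels, fs=fs))
        assert stats.mmd_ms["A"] == pytest.approx(40.0)
        assert stats.mfo_hz["A"] == pytest.approx(10.0)
        assert stats.mc_pct["A"] == pytest.approx(40.0)
        assert stats.mmd_ms["B"] == pytest.approx(60.0)
        assert stats.mfo_hz["B"] == pytest.approx(10.0)
        assert stats.mc_pct["B"] == pytest.approx(60.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_identities_on_random_filtered_sequences(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(-1, 4, size=rng.integers(50, 2000))
        seq = ms.filter_segments(
            LabelSequence(labels=labels, fs=500.0), min_ms=4.0)
        stats = ms.microstate_statistics(seq)
        total_mc = sum(stats.mc_pct.values())
        assert total_mc == pytest.approx(stats.assigned_fraction, abs=1e-9)
        for cls in "ABCD":
            assert stats.mc_pct[cls] == pytest.approx(
                stats.mmd_ms[cls] * stats.mfo_hz[cls] / 10.0, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            LabelSequence(labels=np.array([], dtype=int), fs=500.0)


def test_end_to_end_polarity_invariance(planted_recording, templates):
    rec, _ = planted_recording
    flipped = rec.copy_with(-rec.data)
    rows = []
    for r in (rec, flipped):
        labels = ms.filter_segments(ms.backfit(r, templates))
        rows.append(ms.microstate_statistics(labels).as_row())
    assert rows[0] == rows[1]
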