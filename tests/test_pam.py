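"""Guard-band click detector: spectral arithmetic, normalization,
detection monotonicity, run-length decomposition, absence test."""

import numpy as np
import pandas as pd
import pytest

from sonarcee import pam
from sonarcee import simulate as sim


@pytest.fixture(scope="module")
def click_scene():
    """One-hour PSD scene: clicking in the first half, silence after."""
    cfg = sim.SimConfig(seed=21)
    cfg.pam.duration_s = 3600.0
    cfg.pam.clicking_intervals = [(0.0, 1800.0)]
    spec, truth = sim.make_pam_scene(cfg, "psd")
    return spec, truth


class TestPsdSpectrogram:
    def test_sine_at_bin_centre_parseval(self):
        """Peak at the bin, integrated PSD equals signal power within 1e-6."""
        fs, N = 144_000.0, 8192
        f0 = 200 * fs / N
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        sp = pam.psd_spectrogram(x, fs)
        df = sp.freqs[1] - sp.freqs[0]
        total = sp.psd.sum(axis=1) * df
        assert np.allclose(total, 0.5, rtol=1e-6)
        assert sp.freqs[np.argmax(sp.psd[0])] == pytest.approx(f0)

    def test_white_noise_flat_mean_psd(self, rng):
        fs = 96_000.0
        x = rng.normal(0, 1, int(fs * 5))
        sp = pam.psd_spectrogram(x, fs)
        mean_psd = sp.psd.mean(axis=0)[10:-10]
        assert mean_psd.std() / mean_psd.mean() < 0.1
        df = sp.freqs[1] - sp.freqs[0]
        assert (sp.psd.sum(axis=1) * df).mean() == pytest.approx(1.0, rel=0.05)

    def test_zeros_zero_psd_and_short_audio_rejected(self):
        sp = pam.psd_spectrogram(np.zeros(20_000), 144_000.0)
        assert sp.psd.max() == 0.0
        with pytest.raises(ValueError, match="shorter"):
            pam.psd_spectrogram(np.zeros(100), 144_000.0)

    def test_frame_spacing_half_frame(self):
        sp = pam.psd_spectrogram(np.random.default_rng(0).normal(0, 1, 60_000),
                                 144_000.0)
        dt = np.diff(sp.times)
        assert np.allclose(dt, 4096 / 144_000.0)


class TestNormalizePsd:
    def test_stationary_noise_self_normalizes_near_zero(self, rng):
        freqs = np.linspace(100, 70_000, 120)
        psd = rng.exponential(1e-9, (400, 120))
        spec = sim.PsdSpectrogram(times=np.arange(400) * 0.03, freqs=freqs,
                                  psd=psd, fs=144_000.0, frame_len=8192)
        norm = pam.normalize_psd(spec)
        in_ref = (freqs >= 5000) & (freqs <= 50_000)
        med = np.median(norm.level_db[:, in_ref])
        assert abs(med) < 3.0  # dB; floor sits in the low tail of exponentials

    def test_floor_matches_brute_force(self, rng):
        freqs = np.linspace(100, 70_000, 60)
        psd = rng.exponential(1e-9, (200, 60))
        spec = sim.PsdSpectrogram(times=np.arange(200) * 0.03, freqs=freqs,
                                  psd=psd, fs=144_000.0, frame_len=8192)
        norm = pam.normalize_psd(spec)
        in_ref = (freqs >= 5000) & (freqs <= 50_000)
        lvl = psd[:, in_ref].mean(axis=1)
        sel = lvl <= np.quantile(lvl, 0.05)
        assert np.allclose(norm.floor, psd[sel].mean(axis=0))

    def test_rare_transients_leave_floor_unaffected(self, rng):
        freqs = np.linspace(100, 70_000, 60)
        psd = rng.exponential(1e-9, (200, 60))
        loud = psd.copy()
        loud[::50] *= 1000.0  # 4 loud frames, outside the lowest 5%
        quiet_floor = pam.normalize_psd(
            sim.PsdSpectrogram(np.arange(200) * 0.03, freqs, psd, 144_000.0, 8192)).floor
        loud_floor = pam.normalize_psd(
            sim.PsdSpectrogram(np.arange(200) * 0.03, freqs, loud, 144_000.0, 8192)).floor
        assert np.allclose(quiet_floor, loud_floor)

    def test_few_frames_flagged(self, rng):
        freqs = np.linspace(100, 70_000, 30)
        psd = rng.exponential(1e-9, (10, 30))
        with pytest.warns(UserWarning, match="20 frames"):
            norm = pam.normalize_psd(
                sim.PsdSpectrogram(np.arange(10) * 0.03, freqs, psd, 144_000.0, 8192))
        assert norm.flagged


class TestSegmentLevels:
    def test_clicking_segments_large_positive_difference(self, click_scene):
        spec, truth = click_scene
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        labels = pam.segments_truth(truth.click_times, len(segs))
        assert segs.loc[labels, "level_diff_db"].min() > 5.0
        assert segs.loc[~labels, "level_diff_db"].max() < 5.0

    def test_broadband_transient_rejected_by_guard_band(self):
        """A transient covering both bands yields a near-zero difference —
        the design purpose of the guard band."""
        cfg = sim.SimConfig(seed=22)
        cfg.pam.duration_s = 900.0
        cfg.pam.click_rate_hz = 0.0
        cfg.pam.broadband_interferer_times = tuple(np.arange(10.0, 890.0, 2.0))
        spec, _ = sim.make_pam_scene(cfg, "psd")
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        assert np.abs(segs["level_diff_db"]).max() < 5.0

    def test_guard_band_interferers_do_not_trigger(self):
        cfg = sim.SimConfig(seed=23)
        cfg.pam.duration_s = 900.0
        cfg.pam.click_rate_hz = 0.0
        cfg.pam.guard_interferer_times = tuple(np.arange(5.0, 890.0, 2.0))
        spec, _ = sim.make_pam_scene(cfg, "psd")
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        assert segs["level_diff_db"].max() < 0.0

    def test_partial_trailing_segment_dropped(self, click_scene):
        spec, _ = click_scene
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        assert len(segs) == int(spec.times[-1] // 150.0)


class TestDetect:
    def test_threshold_semantics(self):
        segs = pd.DataFrame({"level_diff_db": [6.0]})
        assert pam.detect(segs, 5.0)["detected"][0]
        assert not pam.detect(segs, 8.0)["detected"][0]

    def test_raising_threshold_never_adds_detections(self, click_scene):
        spec, _ = click_scene
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        prev = None
        for thr in np.arange(0.0, 15.0, 1.0):
            n = int(pam.detect(segs, thr)["detected"].sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_gain_invariance_of_level_differences(self):
        """Multiplying the audio by a constant gain leaves all level
        differences unchanged (self-normalized statistic)."""
        cfg = sim.SimConfig(seed=24)
        cfg.pam.duration_s = 40.0
        cfg.pam.click_rate_hz = 2.0
        wav, _ = sim.make_pam_scene(cfg, "audio")
        fs = cfg.pam.fs

        def diffs(x):
            norm = pam.normalize_psd(pam.psd_spectrogram(x, fs))
            in_e = (norm.freqs >= 20_000) & (norm.freqs <= 40_000)
            in_g = (norm.freqs >= 4_000) & (norm.freqs <= 8_000)
            lin = 10 ** (norm.level_db / 10.0)
            return (10 * np.log10(lin[:, in_e].mean(1))
                    - 10 * np.log10(lin[:, in_g].mean(1)))

        assert np.allclose(diffs(wav), diffs(3.7 * wav), atol=1e-9)


class TestRoc:
    def test_perfect_separation(self, click_scene):
        spec, truth = click_scene
        segs = pam.segment_level_difference(pam.normalize_psd(spec))
        labels = pam.segments_truth(truth.click_times, len(segs))
        roc = pam.roc_tune(segs, labels, np.array([5.0]))
        assert roc["precision"][0] == 1.0 and roc["recall"][0] == 1.0

    def test_all_negative_truth_flagged(self, rng):
        segs = pd.DataFrame({"level_diff_db": rng.normal(-2, 0.5, 30)})
        with pytest.warns(UserWarning, match="recall undefined"):
            roc = pam.roc_tune(segs, np.zeros(30, dtype=bool), np.array([5.0]))
        assert np.isnan(roc["recall"][0])

    def test_counts_match_brute_force(self, rng):
        score = rng.normal(3.0, 3.0, 200)
        truth = rng.random(200) < 0.4
        segs = pd.DataFrame({"level_diff_db": score})
        roc = pam.roc_tune(segs, truth, np.array([2.0, 4.0, 6.0]))
        for _, row in roc.iterrows():
            det = score >= row["threshold_db"]
            assert row["tp"] == np.sum(det & truth)
            assert row["fp"] == np.sum(det & ~truth)
            assert row["fn"] == np.sum(~det & truth)


class TestAbsentPeriods:
    def test_enumerated_example(self):
        det = np.zeros(6, dtype=bool)
        det[[1, 5]] = True
        runs = pam.click_absent_periods(det)
        assert len(runs.periods) == 2
        internal = runs.periods.iloc[1]
        assert internal["n_segments"] == 3
        assert internal["duration_h"] == pytest.approx(3 * 150 / 3600.0)

    def test_all_detected_no_periods(self):
        runs = pam.click_absent_periods(np.ones(10, dtype=bool))
        assert runs.periods.empty

    def test_matches_brute_force_run_lengths(self, rng):
        det = rng.random(500) < 0.5
        runs = pam.click_absent_periods(det)
        # partition property: run lengths + detected count = total segments
        assert runs.periods["n_segments"].sum() + det.sum() == 500
        # brute-force RLE
        expect = []
        count = 0
        for d in det:
            if not d:
                count += 1
            elif count:
                expect.append(count)
                count = 0
        if count:
            expect.append(count)
        assert runs.periods["n_segments"].tolist() == expect

    def test_short_runs_excluded_from_baseline(self):
        det = np.ones(30, dtype=bool)
        det[3:7] = False  # 4 segments = 10 min, excluded (<= 10 min)
        det[10:20] = False  # 25 min, kept
        runs = pam.click_absent_periods(det)
        assert len(runs.periods) == 2
        assert runs.baseline_durations_h.tolist() == [pytest.approx(10 * 150 / 3600)]


class TestAbsenceOutlierTest:
    def _baseline(self):
        return np.tile([0.5, 1.0, 2.0, 4.0], 20)

    def test_below_median_no_response(self):
        res = pam.absence_outlier_test(0.6, self._baseline())
        assert not res.response

    def test_above_maximum_response_percentile_one(self):
        res = pam.absence_outlier_test(5.0, self._baseline())
        assert res.response and res.percentile == 1.0

    def test_straddling_the_quantile(self):
        base = self._baseline()
        q95 = np.quantile(base, 0.95)
        assert not pam.absence_outlier_test(q95 - 0.1, base).response
        assert pam.absence_outlier_test(q95 + 0.1, base).response

    def test_small_baseline_flagged_low_power(self):
        with pytest.warns(UserWarning, match="low power"):
            res = pam.absence_outlier_test(3.0, np.array([1.0, 2.0]))
        assert res.low_power

    def test_empty_baseline_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            pam.absence_outlier_test(3.0, np.array([]))
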