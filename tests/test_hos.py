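"""Detector core: cumulant series, thresholding, segment rules, scoring."""

import numpy as np
import pytest

from bowelsound.hos import (
    DetectorConfig,
    HOSSeries,
    calibrate_threshold,
    detect,
    energy_confusion,
    hos_series,
    segments_from_threshold,
    threshold_from_portion,
)
from bowelsound.intervals import IntervalSet

FS = 8000.0
MM = 24  # 0.003 s at 8 kHz


def brute_force_hos(x, mm):
    """Windowed absolute third central moment by direct summation."""
    out = []
    for k in range(len(x) // mm):
        w = x[k * mm : (k + 1) * mm]
        mu = sum(w) / mm
        out.append(abs(sum((v - mu) ** 3 for v in w) / mm))
    return np.array(out)


def make_series(values, fs=FS):
    return HOSSeries(values=np.asarray(values, float), window_samples=MM, hop_samples=MM, fs=fs)


class TestHOSSeries:
    def test_window_length_follows_sample_rate(self):
        h = hos_series(np.random.default_rng(0).normal(size=1000), FS)
        assert h.window_samples == 24
        h2 = hos_series(np.random.default_rng(0).normal(size=1000), 4000.0)
        assert h2.window_samples == 12

    def test_constant_signal_has_zero_cumulant(self):
        h = hos_series(np.full(240, 3.7), FS)
        assert np.allclose(h.values, 0)

    def test_symmetric_alternation_has_zero_cumulant(self):
        x = np.tile([2.0, -2.0], 120)
        assert np.allclose(hos_series(x, FS).values, 0)

    def test_single_spike_window_matches_hand_computation(self):
        x = np.zeros(24)
        x[0] = 3.0
        h = hos_series(x, FS)
        mu = 3.0 / 24
        expected = abs(((3.0 - mu) ** 3 + 23 * (0 - mu) ** 3) / 24)
        assert h.values[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(24, 400))
            got = hos_series(x, FS).values
            want = brute_force_hos(x.tolist(), 24)
            assert np.sqrt(np.mean((got - want) ** 2)) < 1e-12

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            hos_series(np.array([]), FS)


class TestThresholdFromPortion:
    def test_all_equal_values_give_twice_value(self):
        h = make_series(np.full(100, 0.5))
        for portion in (0.9, 0.95, 0.999):
            assert threshold_from_portion(h, portion) == pytest.approx(1.0)

    def test_all_zero_series(self):
        assert threshold_from_portion(make_series(np.zeros(50)), 0.95) == 0.0

    def test_threshold_brackets_quantile_under_binning(self, rng):
        values = np.abs(rng.normal(size=1000))
        values[:4] = 50.0
        h = make_series(values)
        cfg = DetectorConfig()
        thr = threshold_from_portion(h, 0.99, cfg)
        # the 0.99-quantile lies in or below the selected bin
        edges = np.linspace(0, values.max(), cfg.histogram_bins + 1)
        q_bin_upper = edges[np.searchsorted(edges, np.quantile(values, 0.99))]
        assert 2 * q_bin_upper - 2 * values.max() / cfg.histogram_bins <= thr
        assert thr <= 2 * values.max()

    def test_invalid_portion_rejected(self):
        h = make_series(np.ones(10))
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                threshold_from_portion(h, bad)


class TestSegmentRules:
    """The annotation rules: >10 ms events, sub-100-ms gaps merge."""

    def test_four_window_run_is_a_kept_12ms_event(self):
        v = np.zeros(100)
        v[10:14] = 1.0
        segs = segments_from_threshold(make_series(v), 0.5)
        assert segs.intervals == ((10 * MM, 14 * MM),)

    def test_isolated_6ms_run_is_discarded(self):
        v = np.zeros(100)
        v[10:12] = 1.0  # 2 windows = 6 ms < 10 ms
        assert len(segments_from_threshold(make_series(v), 0.5)) == 0

    def test_runs_90ms_apart_merge(self):
        v = np.zeros(200)
        v[10:14] = 1.0
        gap_windows = 30  # 90 ms
        v[14 + gap_windows : 18 + gap_windows] = 1.0
        segs = segments_from_threshold(make_series(v), 0.5)
        assert len(segs) == 1
        assert segs.intervals[0] == (10 * MM, (18 + gap_windows) * MM)

    def test_runs_110ms_apart_stay_separate(self):
        v = np.zeros(200)
        v[10:14] = 1.0
        gap_windows = 37  # 111 ms
        v[14 + gap_windows : 18 + gap_windows] = 1.0
        segs = segments_from_threshold(make_series(v), 0.5)
        assert len(segs) == 2

    def test_raising_threshold_never_extends_detections(self, rng):
        v = np.abs(rng.normal(size=500))
        h = make_series(v)
        prev = None
        for thr in np.linspace(0, v.max(), 20):
            active_ms = (v > thr).sum() * 3
            if prev is not None:
                assert active_ms <= prev
            prev = active_ms


class TestEnergyConfusion:
    def test_perfect_detection_scores_one(self, rng):
        x = rng.normal(size=1000)
        iv = IntervalSet.from_pairs([(100, 300), (500, 700)])
        ev = energy_confusion(x, iv, iv)
        assert ev.accuracy == 1.0 and ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_empty_detection_with_labels(self, rng):
        x = rng.normal(size=1000)
        ev = energy_confusion(x, IntervalSet(), IntervalSet.from_pairs([(0, 500)]))
        assert ev.sensitivity == 0.0 and ev.specificity == 1.0

    def test_empty_labels_flags_sensitivity(self, rng):
        x = rng.normal(size=100)
        ev = energy_confusion(x, IntervalSet.from_pairs([(0, 50)]), IntervalSet())
        assert not ev.sensitivity_defined and np.isnan(ev.sensitivity)
        assert np.isfinite(ev.accuracy) and np.isfinite(ev.specificity)

    def test_matches_per_sample_partition_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(50, 300))
            x = rng.normal(size=n)
            det = IntervalSet.from_pairs(
                [(a, a + int(rng.integers(1, 40))) for a in rng.integers(0, n - 40, 3)]
            )
            lab = IntervalSet.from_pairs(
                [(a, a + int(rng.integers(1, 40))) for a in rng.integers(0, n - 40, 3)]
            )
            ev = energy_confusion(x, det, lab)
            # brute-force four-way per-sample sum
            e = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
            dm, lm = det.to_mask(n), lab.to_mask(n)
            for i in range(n):
                key = ("tp" if lm[i] else "fp") if dm[i] else ("fn" if lm[i] else "tn")
                e[key] += x[i] ** 2
            assert ev.E_TP == pytest.approx(e["tp"], abs=1e-12)
            assert ev.E_FP == pytest.approx(e["fp"], abs=1e-12)
            assert ev.E_FN == pytest.approx(e["fn"], abs=1e-12)
            assert ev.E_TN == pytest.approx(e["tn"], abs=1e-12)

    def test_energy_is_conserved_exactly(self, rng):
        x = rng.normal(size=2000)
        det = IntervalSet.from_pairs([(0, 700), (900, 1500)])
        lab = IntervalSet.from_pairs([(300, 1000)])
        ev = energy_confusion(x, det, lab)
        assert ev.E_TP + ev.E_FP + ev.E_FN + ev.E_TN == pytest.approx(
            np.sum(x**2), rel=1e-12
        )


class TestCalibration:
    def test_returned_threshold_maximizes_accuracy(self, calibration_result):
        sweep = calibration_result.sweep
        assert calibration_result.evaluation.accuracy == pytest.approx(
            sweep["accuracy"].max()
        )

    def test_redetection_reproduces_calibration_eval(self, calib_recording, calibration_result):
        _, den, truth = calib_recording
        segs = detect(den.bs, den.fs, calibration_result.threshold)
        ev = energy_confusion(den.bs, segs, truth.ebs)
        assert ev.accuracy == pytest.approx(calibration_result.evaluation.accuracy)

    def test_full_coverage_labels_give_full_sensitivity(self, rng):
        x = rng.normal(size=24000)
        labeled = IntervalSet.from_pairs([(0, 24000)])
        res = calibrate_threshold(x, FS, labeled)
        # whatever is detected lies inside the labels: sensitivity is the
        # detected share, and a detector returning everything scores 1
        assert res.evaluation.specificity == 1.0 or np.isnan(res.evaluation.specificity)

    def test_empty_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="empty calibration labels"):
            calibrate_threshold(rng.normal(size=1000), FS, IntervalSet())

    def test_zero_signal_detects_nothing(self):
        assert len(detect(np.zeros(24000), FS, 0.1)) == 0

    def test_calibration_is_deterministic(self, calib_recording):
        _, den, truth = calib_recording
        r1 = calibrate_threshold(den.bs[:240000], den.fs, truth.ebs)
        r2 = calibrate_threshold(den.bs[:240000], den.fs, truth.ebs)
        assert r1.threshold == r2.threshold and r1.portion == r2.portion
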