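"""Characteristic values: closed forms, oracles, invariances."""

import numpy as np
import pytest

import bowelsound as bs
from bowelsound.features import (
    EntropyParams,
    extract_all,
    freq_domain_cvs,
    katz_fd,
    sample_entropy,
    stage_ebs_frequency,
    time_domain_cvs,
)
from bowelsound.intervals import IntervalSet

FS = 8000.0


class TestTimeDomain:
    def test_duration_from_length(self):
        _, _, dur = time_domain_cvs(np.ones(80), FS)
        assert dur == pytest.approx(10.0)

    def test_constant_magnitude_has_zero_cv(self):
        cv, e0, _ = time_domain_cvs(np.array([1.0, -1.0, 1.0, -1.0]), FS)
        assert cv == 0.0 and e0 == pytest.approx(4.0)

    def test_energy_matches_direct_sum(self, rng):
        x = rng.normal(size=500)
        _, e0, _ = time_domain_cvs(x, FS)
        assert e0 == pytest.approx(sum(v * v for v in x), rel=1e-12)

    def test_energy_invariant_under_sign_flip(self, rng):
        x = rng.normal(size=100)
        assert time_domain_cvs(x, FS)[1] == time_domain_cvs(-x, FS)[1]

    def test_zero_segment_flags_cv(self):
        cv, e0, _ = time_domain_cvs(np.zeros(50), FS)
        assert np.isnan(cv) and e0 == 0.0


class TestFreqDomain:
    def _tone(self, freq, n=2048):
        return np.sin(2 * np.pi * freq * np.arange(n) / FS + 0.3)

    def test_pure_tone_centroid_and_band(self):
        fc, er1, er2, er3 = freq_domain_cvs(self._tone(200.0), FS)
        bin_hz = FS / 2048
        assert abs(fc - 200.0) <= bin_hz
        assert er1 >= 0.99 and er3 <= 0.01

    def test_two_tone_centroid_is_midpoint(self):
        x = self._tone(100.0) + self._tone(300.0)
        fc, *_ = freq_domain_cvs(x, FS)
        assert abs(fc - 200.0) <= FS / 2048

    def test_high_tone_in_upper_band(self):
        fc, er1, er2, er3 = freq_domain_cvs(self._tone(700.0), FS)
        assert er3 >= 0.99 and er1 <= 0.01

    def test_fractions_bounded_and_centroid_in_range(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(64, 1000)))
            fc, er1, er2, er3 = freq_domain_cvs(x, FS)
            assert 0 <= fc <= FS / 2
            assert all(0 <= e <= 1 for e in (er1, er2, er3))
            assert er1 + er2 + er3 <= 1 + 1e-9


class TestKatzFD:
    def test_affine_segment_is_exactly_one(self):
        for slope in (0.5, -2.0, 13.7):
            x = slope * np.arange(50) + 3.0
            assert katz_fd(x) == pytest.approx(1.0, abs=1e-12)

    def test_triangle_hand_computation(self):
        # points (0,0),(1,1),(2,0): L = 2*sqrt(2), d = 2
        fd = katz_fd(np.array([0.0, 1.0, 0.0]))
        assert fd == pytest.approx(np.log10(2 * np.sqrt(2)) / np.log10(2.0), rel=1e-12)

    def test_random_walk_exceeds_one(self, rng):
        x = np.cumsum(rng.choice([-1.0, 1.0], size=1000))
        assert katz_fd(x) > 1.0

    def test_constant_segment_is_flagged(self):
        assert np.isnan(katz_fd(np.full(10, 2.0)))

    def test_normalized_variant_on_affine(self):
        x = 0.7 * np.arange(100)
        assert katz_fd(x, normalized=True) == pytest.approx(1.0, rel=1e-6)


def brute_force_sampen(x, m, r, tau=1):
    """Direct template-counting reference for sample entropy."""
    n = len(x)

    def u(mm):
        n_templates = n - mm * tau
        denom = n - (mm + 1) * tau
        total = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                d = max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(mm))
                if d <= r:
                    total += 1
        return total / n_templates / denom

    um, um1 = u(m), u(m + 1)
    return -np.log(um1 / um)


class TestSampleEntropy:
    def test_constant_segment_is_zero(self):
        assert sample_entropy(np.full(60, 5.0), EntropyParams(r=0.1)) == 0.0

    def test_periodic_pattern_is_perfectly_predictable(self):
        x = np.array([1.0, 2.0] * 40)
        assert sample_entropy(x, EntropyParams(m=2, r=0.1)) == pytest.approx(0.0)

    def test_matches_brute_force_on_noise(self, rng):
        for _ in range(5):
            x = rng.uniform(size=200)
            r = 0.2 * x.std()
            got = sample_entropy(x, EntropyParams(m=2, r=r))
            want = brute_force_sampen(x.tolist(), 2, r)
            assert got == pytest.approx(want, abs=1e-12)

    def test_non_increasing_in_tolerance(self, rng):
        x = rng.normal(size=300)
        vals = [
            sample_entropy(x, EntropyParams(m=2, r=r))
            for r in (0.1, 0.2, 0.5, 1.0)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), EntropyParams(m=2))


class TestStageFrequency:
    def test_three_events_in_one_epoch(self):
        hyp = bs.Hypnogram(labels=("w", "N3"))
        epoch = int(30 * FS)
        ebs = IntervalSet.from_pairs(
            [(100, 200), (1000, 1100), (2000, 2100), (epoch + 50, epoch + 150)]
        )
        rates = stage_ebs_frequency(ebs, hyp, FS)
        assert rates.loc[0, "rate_per_s"] == pytest.approx(0.1)
        assert rates.loc[1, "rate_per_s"] == pytest.approx(1 / 30.0)

    def test_no_events_all_zero(self):
        hyp = bs.Hypnogram(labels=("w", "N1", "N2"))
        rates = stage_ebs_frequency(IntervalSet(), hyp, FS)
        assert (rates["rate_per_s"] == 0).all()

    def test_mean_rate_matches_poisson_intensity(self):
        rate_per_min = 30.0
        cfg = bs.SynthConfig(
            duration_s=600.0, seed=21, ebs_rate_per_min=rate_per_min,
            turnover_rate_per_hour=0.0,
        )
        _, truth = bs.generate(cfg)
        starts = IntervalSet.from_pairs([(e["start"], e["end"]) for e in truth.events])
        rates = stage_ebs_frequency(starts, truth.hypnogram, cfg.fs)
        lam = rate_per_min / 60.0
        n = len(rates)
        sigma = np.sqrt(lam / (30.0 * n))  # SE of the mean per-epoch rate
        assert abs(rates["rate_per_s"].mean() - lam) < 4 * sigma


class TestExtractAll:
    def test_stage_label_from_start_epoch(self):
        hyp = bs.Hypnogram(labels=("w", "N3"))
        fs = 8000.0
        x = np.random.default_rng(0).normal(size=int(60 * fs))
        rec = bs.Recording(bs=x, ns=np.zeros_like(x), fs=fs)
        last_w_sample = int(30 * fs) - 1
        ebs = IntervalSet.from_pairs(
            [(1000, 3000), (last_w_sample, last_w_sample + 2000)]
        )
        records = extract_all(rec, ebs, hyp)
        assert records[0].stage == "w"
        assert records[1].stage == "w"  # start sample decides, even at epoch edge

    def test_synthetic_events_yield_complete_records(self):
        cfg = bs.SynthConfig(duration_s=120.0, seed=13, turnover_rate_per_hour=0.0)
        rec, truth = bs.generate(cfg)
        records = extract_all(rec, truth.ebs, truth.hypnogram)
        assert len(records) == len(truth.ebs)
        for r in records:
            assert r.E0 > 0 and r.duration_ms > 0
            assert r.stage in ("w", "N1", "N2", "N3", "REM")
            # every field is a float (finite or flagged NaN), never raises
            for col in ("cv", "FC", "ER_5_300", "FD", "SampEn"):
                assert isinstance(getattr(r, col), float)
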