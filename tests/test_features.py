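"""Tests for epoch extraction and the per-epoch feature estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import nmprobe as nm
from nmprobe.features import extract_epochs


class TestExtractEpochs:
    def test_epoch_count_schedule_arithmetic(self, background_run):
        # 100 s run, onsets at 2, 4, ..., 98; each 400 ms window fits
        em = extract_epochs(background_run)
        assert em.epochs.shape == (2, 49, int(np.floor(0.400 / 0.00195)))
        assert em.epochs.shape[2] == 205

    def test_full_length_run_epoch_count(self, default_config):
        """2000 s at period 2 s starting at 2 s yields 999 complete epochs."""
        onsets = nm.StimulusProtocol(amplitude=0.0).onset_times(2000.0)
        n_complete = np.sum(onsets + 0.400 <= 2000.0)
        assert len(onsets) == 999 and n_complete == 999

    def test_passive_and_probed_schedules_align(self, default_config):
        setting = nm.ModelSetting("x", default_config, None, (1, 2))
        spec = nm.IntegrationSpec(duration=30.0, seed=9)
        r0 = nm.integrate(setting, nm.StimulusProtocol(amplitude=0.0), spec)
        r1 = nm.integrate(setting, nm.StimulusProtocol(amplitude=120.0), spec)
        e0, e1 = extract_epochs(r0), extract_epochs(r1)
        np.testing.assert_array_equal(e0.onset_times, e1.onset_times)

    def test_window_longer_than_period_rejected(self, background_run):
        with pytest.raises(ValueError):
            extract_epochs(background_run, window_s=2.5)


class TestMomentFeatures:
    def test_constant_epoch(self):
        var, skw, kur = nm.moment_features(np.full(100, 3.3))
        assert var == 0.0 and np.isnan(skw) and np.isnan(kur)

    def test_symmetric_epoch_zero_skewness(self):
        var, skw, kur = nm.moment_features(np.tile([-1.0, 1.0], 102))
        assert var == pytest.approx(1.0)
        assert skw == pytest.approx(0.0, abs=1e-12)
        assert kur == pytest.approx(1.0)  # two-point symmetric distribution

    def test_gaussian_sample_moments(self, rng):
        x = rng.standard_normal(10 ** 4)
        var, skw, kur = nm.moment_features(x)
        assert var == pytest.approx(1.0, abs=0.05)
        assert skw == pytest.approx(0.0, abs=0.1)
        assert kur == pytest.approx(3.0, abs=0.2)  # Pearson convention

    def test_matches_brute_force_definitions(self, rng):
        for _ in range(20):
            x = rng.normal(2, 3, 50)
            var, skw, kur = nm.moment_features(x)
            m = x.sum() / len(x)
            m2 = sum((v - m) ** 2 for v in x) / len(x)
            m3 = sum((v - m) ** 3 for v in x) / len(x)
            m4 = sum((v - m) ** 4 for v in x) / len(x)
            assert var == pytest.approx(m2, rel=1e-10)
            assert skw == pytest.approx(m3 / m2 ** 1.5, rel=1e-10)
            assert kur == pytest.approx(m4 / m2 ** 2, rel=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nm.moment_features([1.0, 2.0, 3.0])


class TestLag1Autocorrelation:
    def test_alternating_closed_form(self):
        for n in (10, 100, 204):
            x = np.tile([1.0, -1.0], n // 2)
            assert nm.lag1_autocorrelation(x) == pytest.approx(-(n - 1) / n, rel=1e-12)

    def test_monotone_ramp_near_one(self):
        assert nm.lag1_autocorrelation(np.arange(204.0)) > 0.95

    def test_white_noise_near_zero(self, rng):
        vals = [nm.lag1_autocorrelation(rng.standard_normal(204)) for _ in range(50)]
        assert np.mean(np.abs(vals) < 0.2) > 0.9

    def test_constant_is_undefined(self):
        assert np.isnan(nm.lag1_autocorrelation(np.ones(10)))


class TestMutualInformation:
    def test_identical_two_level_epochs_give_one_bit(self):
        x = np.tile([0.0, 1.0], 100)
        assert nm.mutual_information(x, x, n_bins=2) == pytest.approx(1.0)

    def test_self_information_equals_entropy(self, rng):
        x = rng.standard_normal(204)
        counts, _ = np.histogram(x, bins=16)
        p = counts / counts.sum()
        H = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert nm.mutual_information(x, x) == pytest.approx(H, rel=1e-10)

    def test_independent_epochs_small_positive(self, rng):
        n, bins = 5000, 16
        mi = nm.mutual_information(rng.standard_normal(n), rng.standard_normal(n), bins)
        bias_bound = (bins - 1) ** 2 / (2 * n * np.log(2))
        assert 0.0 <= mi < 3 * bias_bound

    def test_constant_epoch_gives_zero(self, rng):
        assert nm.mutual_information(np.ones(50), rng.standard_normal(50)) == 0.0

    @given(arrays(float, 64, elements=st.floats(-10, 10)),
           arrays(float, 64, elements=st.floats(-10, 10)))
    @settings(max_examples=30, deadline=None)
    def test_non_negative(self, x, y):
        assert nm.mutual_information(x, y) >= -1e-12

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            nm.mutual_information(np.ones(5), np.ones(6))


class TestSmooth:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(nm.smooth(np.full(100, 2.5)), np.full(100, 2.5))

    def test_impulse_response_spreads(self):
        x = np.zeros(60)
        x[25] = 1.0
        s = nm.smooth(x, order=20)
        np.testing.assert_allclose(s[25:45], [1 / min(k + 1, 20) for k in range(25, 45)])
        assert np.all(s[45:] == 0.0) and np.all(s[:25] == 0.0)

    def test_prefix_rule_short_series(self):
        x = np.arange(10.0)
        s = nm.smooth(x, order=20)
        np.testing.assert_allclose(s, [np.mean(x[:k + 1]) for k in range(10)])

    def test_missing_values_skipped(self):
        x = np.array([1.0, np.nan, 3.0, 5.0])
        s = nm.smooth(x, order=2)
        np.testing.assert_allclose(s, [1.0, 1.0, 3.0, 4.0])

    def test_preserves_length_and_centered_option(self, rng):
        x = rng.standard_normal(57)
        assert len(nm.smooth(x)) == 57
        assert len(nm.smooth(x, centered=True)) == 57


class TestFeatureInvariances:
    def test_offset_invariance(self, rng):
        """All five features ignore a constant LFP offset."""
        x = rng.standard_normal(204)
        y = rng.standard_normal(204)
        for off in (5.0, -13.2):
            assert nm.moment_features(x + off) == pytest.approx(nm.moment_features(x))
            assert nm.lag1_autocorrelation(x + off) == pytest.approx(
                nm.lag1_autocorrelation(x))
            assert nm.mutual_information(x + off, y) == pytest.approx(
                nm.mutual_information(x, y))

    def test_scale_behaviour(self, rng):
        """Standardized moments, lag-1 AC and MI are scale-free; variance scales as c^2."""
        x = rng.standard_normal(204)
        y = rng.standard_normal(204)
        c = 3.7
        v0, s0, k0 = nm.moment_features(x)
        v1, s1, k1 = nm.moment_features(c * x)
        assert v1 == pytest.approx(c ** 2 * v0)
        assert (s1, k1) == pytest.approx((s0, k0))
        assert nm.lag1_autocorrelation(c * x) == pytest.approx(nm.lag1_autocorrelation(x))
        assert nm.mutual_information(c * x, y) == pytest.approx(nm.mutual_information(x, y))

    def test_pipeline_series_lengths(self, background_run):
        fs = nm.compute_features(background_run)
        n = len(fs.epoch_times)
        for name, v in fs.values.items():
            assert v.shape[-1] == n
            assert fs.smoothed[name].shape == v.shape
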