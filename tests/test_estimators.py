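import numpy as np
import pytest

import measpike as mp
from measpike.estimators import INVALID, AdaBandFlt, AdaFlt, AdaFlt128, BandFlt, Limada
from measpike.preprocess import WindowView, window_length
from measpike.recording import Recording

WL = 250  # 10 ms at 25 kHz


def constant_windows(amplitude, n):
    return [np.full(WL, amplitude) for _ in range(n)]


def bipolar_window(amplitude):
    """A window whose max is +amplitude and min is -amplitude."""
    w = np.zeros(WL)
    w[10], w[20] = amplitude, -amplitude
    return w


class TestThresholdsFromEstimate:
    def test_symmetric(self):
        t = mp.thresholds_from_estimate(2.5, 4.0)
        assert (t.pos, t.neg) == (10.0, -10.0)

    def test_asymmetric_pair(self):
        t = mp.thresholds_from_estimate((3.0, -2.0), 2.0)
        assert (t.pos, t.neg) == (6.0, -4.0)

    def test_degenerate_multiplier_rejected(self):
        with pytest.raises(ValueError):
            mp.thresholds_from_estimate(1.0, 0.0)

    def test_negative_estimate_rejected(self):
        with pytest.raises(ValueError):
            mp.thresholds_from_estimate(-1.0, 4.0)


class TestBandFlt:
    def test_constant_windows_give_4x_amplitude(self):
        est = BandFlt()
        for w in constant_windows(3.0, 300):
            t = est.process_window(w)
        assert t.valid
        assert t.pos == pytest.approx(12.0)
        assert t.neg == pytest.approx(-12.0)

    def test_invalid_until_300_windows(self):
        est = BandFlt()
        for w in constant_windows(1.0, 299):
            t = est.process_window(w)
        assert not t.valid
        t = est.process_window(np.full(WL, 1.0))
        assert t.valid

    def test_threshold_fixed_after_init(self):
        est = BandFlt()
        for w in constant_windows(1.0, 300):
            est.process_window(w)
        t0 = est.process_window(np.full(WL, 50.0))
        assert t0.pos == pytest.approx(4.0)

    def test_gaussian_noise_esteem_slightly_below_sigma(self, rng):
        # Monte-Carlo: the 25th percentile of the window-RMS sampling
        # distribution for 250 iid N(0,1) samples sits just under 1
        est = BandFlt()
        for _ in range(300):
            t = est.process_window(rng.standard_normal(WL))
        assert 0.95 < est.noise_est < 1.00


class TestLimadaCleanTest:
    def test_pure_gaussian_is_clean(self, rng):
        # standard-normal quantile oracle: V.02/V.30 ~ 2.054/0.524 ~ 3.9 < 5
        clean, v02, v30 = mp.limada_is_clean(rng.standard_normal(WL))
        assert clean
        assert v02 / v30 == pytest.approx(3.9, abs=1.0)

    def test_spike_contaminated_window_is_dirty(self, rng):
        w = rng.standard_normal(WL)
        w[:10] = -100.0  # a large negative AP drives V.02 far out
        clean, v02, v30 = mp.limada_is_clean(w)
        assert not clean
        assert v02 / v30 > 5

    def test_blanked_window_is_dirty(self):
        clean, _, v30 = mp.limada_is_clean(np.zeros(WL))
        assert not clean
        assert v30 == 0.0


class TestLimada:
    def _clean_window(self, v02_abs):
        # sorted window: 5 samples at -v02_abs (the 2nd-percentile slot),
        # 100 at -1 (the 30th-percentile slot), rest at +1 -> ratio < 5
        return np.concatenate(
            [np.full(5, -v02_abs), np.full(100, -1.0), np.full(145, 1.0)]
        )

    def test_update_rule_substitution(self):
        est = Limada()
        est.noise_est = 2.0
        t = est.process_window(self._clean_window(3.0))
        assert est.noise_est == pytest.approx(2.01)
        assert t.pos == pytest.approx(4 * 2.01)

    def test_initializes_after_100_clean_windows(self):
        est = Limada()
        for i in range(99):
            t = est.process_window(self._clean_window(2.0))
        assert not t.valid
        t = est.process_window(self._clean_window(2.0))
        assert t.valid
        assert est.noise_est == pytest.approx(2.0)  # mean of collected |V.02|

    def test_dirty_window_leaves_state_unchanged(self, rng):
        est = Limada()
        est.noise_est = 2.0
        dirty = rng.standard_normal(WL)
        dirty[:10] = -100.0
        before = est.noise_est
        est.process_window(dirty)
        assert est.noise_est == before

    def test_fixed_point_convergence(self):
        est = Limada()
        est.noise_est = 10.0
        for _ in range(2000):
            est.process_window(self._clean_window(3.0))
        assert est.noise_est == pytest.approx(3.0, abs=1e-6)


class TestAdaFlt:
    def test_init_from_128_window_extrema(self):
        est = AdaFlt()
        for _ in range(128):
            t = est.process_window(bipolar_window(10.0))
        assert t.valid
        # 40th percentile of constant extrema is the value itself; x2
        assert t.pos == pytest.approx(20.0)
        assert t.neg == pytest.approx(-20.0)

    def test_decimation_ten_refreshes_every_1280_windows(self):
        est = AdaFlt()
        for _ in range(128):
            est.process_window(bipolar_window(10.0))
        for _ in range(1279):
            t = est.process_window(bipolar_window(20.0))
        assert t.pos == pytest.approx(20.0)  # not yet refreshed
        t = est.process_window(bipolar_window(20.0))
        assert t.pos == pytest.approx(2 * (0.9 * 10 + 0.1 * 20))

    def test_adaflt128_adapts_faster_than_adaflt(self):
        # step change in noise level: the undecimated variant reaches the
        # new level in an order of magnitude fewer raw windows
        results = {}
        for cls in (AdaFlt, AdaFlt128):
            est = cls()
            for _ in range(128):
                est.process_window(bipolar_window(10.0))
            n = 0
            while est.noise_est_p < 19.0:
                est.process_window(bipolar_window(20.0))
                n += 1
                assert n < 100_000
            results[cls.__name__] = n
        assert results["AdaFlt128"] * 5 < results["AdaFlt"]

    def test_symmetric_noise_gives_symmetric_estimates(self, rng):
        est = AdaFlt128()
        for _ in range(1024):
            est.process_window(rng.standard_normal(WL))
        assert abs(est.noise_est_p + est.noise_est_n) < 0.2 * est.noise_est_p


class TestAdaBandFlt:
    def test_update_rule_substitution(self):
        est = AdaBandFlt()
        for w in constant_windows(1.0, 100):
            t = est.process_window(w)
        assert t.valid and est.noise_est == pytest.approx(1.0)
        for w in constant_windows(1.5, 100):
            t = est.process_window(w)
        assert est.noise_est == pytest.approx(0.8 * 1.0 + 0.2 * 1.5)
        assert t.pos == pytest.approx(4 * 1.1)

    def test_refresh_only_every_100_windows(self):
        est = AdaBandFlt()
        for w in constant_windows(1.0, 100):
            est.process_window(w)
        for w in constant_windows(9.0, 99):
            t = est.process_window(w)
        assert t.pos == pytest.approx(4.0)

    def test_step_response_residual_geometric(self):
        # after m refreshes of the 0.8-smoother, 0.8^m of a step remains
        est = AdaBandFlt()
        for w in constant_windows(1.0, 100):
            est.process_window(w)
        for w in constant_windows(2.0, 1000):
            est.process_window(w)
        assert (2.0 - est.noise_est) == pytest.approx(0.8**10 * 1.0, rel=1e-9)


class TestSmootherClosedForms:
    """Each update equation is an exponential smoother; after m
    constant-input refreshes the estimate equals c + (init - c) * lam^m."""

    def test_adabandflt_lambda_08(self):
        est = AdaBandFlt()
        for w in constant_windows(5.0, 100):
            est.process_window(w)
        m = 7
        for w in constant_windows(2.0, 100 * m):
            est.process_window(w)
        assert est.noise_est == pytest.approx(2.0 + (5.0 - 2.0) * 0.8**m, abs=1e-12)

    def test_adaflt128_lambda_09(self):
        est = AdaFlt128()
        for _ in range(128):
            est.process_window(bipolar_window(5.0))
        m = 6
        for _ in range(128 * m):
            est.process_window(bipolar_window(2.0))
        assert est.noise_est_p == pytest.approx(2.0 + 3.0 * 0.9**m, abs=1e-12)
        assert est.noise_est_n == pytest.approx(-2.0 - 3.0 * 0.9**m, abs=1e-12)

    def test_limada_lambda_099(self):
        est = Limada()
        est.noise_est = 5.0
        w = np.concatenate([np.full(5, -2.0), np.full(100, -1.0), np.full(145, 1.0)])
        m = 50
        for _ in range(m):
            est.process_window(w)
        assert est.noise_est == pytest.approx(2.0 + 3.0 * 0.99**m, abs=1e-12)


class TestStreamingContract:
    def test_run_equals_manual_window_loop(self, rng):
        rec = Recording(rng.standard_normal(25_000 * 3), 25_000.0)
        trace = AdaBandFlt().run(rec)
        est = AdaBandFlt()
        manual = [est.process_window(w) for w in WindowView(rec.samples, 250)]
        assert np.array_equal(trace.pos, [t.pos for t in manual])
        assert np.array_equal(trace.valid, [t.valid for t in manual])

    def test_all_estimators_exceed_noise_rms(self):
        # stationary band-limited Gaussian noise: every estimator's positive
        # threshold ends up strictly above the noise RMS (multiplier >= 2)
        fs = 25_000.0
        noise = mp.generate_bandlimited_noise(int(fs) * 30, fs, seed=42)
        rec = Recording(noise, fs)
        rms = np.sqrt(np.mean(noise**2))
        for name in mp.ESTIMATORS:
            trace = mp.make_estimator(name).run(rec)
            assert trace.valid.any(), name
            assert trace.pos[trace.valid].min() > rms, name

    def test_per_sample_backfill_vs_skip(self):
        est = BandFlt()
        rec = Recording(np.ones(250 * 400), 25_000.0)
        trace = est.run(rec)
        pos_b, _, ok_b = trace.per_sample(rec.n_samples, pre_init="backfill")
        pos_s, _, ok_s = trace.per_sample(rec.n_samples, pre_init="skip")
        first = 300 * 250 - 250  # first sample of the window where init lands
        assert ok_b.all()
        assert not ok_s[:first].any()
        assert pos_b[0] == pytest.approx(4.0)

    def test_unknown_estimator_name(self):
        with pytest.raises(ValueError, match="unknown estimator"):
            mp.make_estimator("median")
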