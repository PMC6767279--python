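import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezosleep import (
    RateState,
    SimConfig,
    SmoothingParams,
    accuracy,
    estimate_alpha,
    find_peaks,
    half_window,
    heart_rate,
    residual,
    respiratory_rate,
    simulate,
    smooth,
)
from piezosleep.errors import DegenerateSignalError, ParameterError, WindowError
from piezosleep.signal_model import PeriodWindow
from conftest import make_window

FS = 100.0


def smooth_oracle(x, W):
    """Direct-sum evaluation of the centered moving average with symmetric
    growing edge windows (1-based indexing as in the defining formulas)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    out = np.empty(N)
    for n in range(1, N + 1):
        if W < n <= N - W:
            lo, hi = n - W, n + W
        elif n <= W:
            lo, hi = 1, 2 * n - 1
        else:
            lo, hi = 2 * n - N, N
        out[n - 1] = x[lo - 1 : hi].sum() / (hi - lo + 1)
    return out


class TestHalfWindow:
    @pytest.mark.parametrize(
        "rate,expected", [(0.3, 83), (1.25, 20), (0.5, 50), (2.0, 12)]
    )
    def test_reference_values(self, rate, expected):
        assert half_window(100.0, rate) == expected

    def test_minimum_one_sample(self):
        assert half_window(10.0, 5.0) == 1

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            half_window(100.0, 0.0)


class TestSmooth:
    def test_constant_series_reproduced_everywhere(self):
        out = smooth(np.full(41, 3.7), 5)
        np.testing.assert_allclose(out, 3.7, rtol=0, atol=1e-12)

    def test_unit_impulse_window_5(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = smooth(x, 2)
        expected = smooth_oracle(x, 2)
        np.testing.assert_allclose(out, expected, atol=1e-15)
        # centered positions within +-W of the impulse average to 1/5
        np.testing.assert_allclose(out[3:8], 0.2)
        np.testing.assert_allclose(out[2], 0.0)
        np.testing.assert_allclose(out[8], 0.0)

    def test_linear_ramp_unchanged(self):
        # symmetric windows (interior and edges) preserve a linear function
        x = np.arange(21, dtype=float)
        np.testing.assert_allclose(smooth(x, 4), x, atol=1e-12)

    def test_window_too_large_raises(self):
        with pytest.raises(WindowError):
            smooth(np.zeros(10), 5)

    @settings(deadline=None, max_examples=40)
    @given(
        n=st.integers(min_value=3, max_value=120),
        w_frac=st.floats(0.01, 0.99),
        seed=st.integers(0, 10_000),
    )
    def test_matches_direct_sum_oracle(self, n, w_frac, seed):
        W = max(1, int(w_frac * (n - 1) / 2))
        x = np.random.default_rng(seed).normal(size=n)
        np.testing.assert_allclose(smooth(x, W), smooth_oracle(x, W), atol=1e-12)

    def test_interior_shift_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        W = 10
        a = smooth(x, W)
        b = smooth(np.roll(x, 7), W)
        # away from both edges, smoothing commutes with the shift
        np.testing.assert_allclose(a[W : 150 - W], b[W + 7 : 157 - W], atol=1e-12)


class TestAlphaAndResidual:
    def test_identity_when_no_smoothing_effect(self):
        x = np.random.default_rng(0).uniform(1, 2, size=101)
        assert estimate_alpha(x, x, 50, 10) == pytest.approx(1.0)

    def test_proportional_series(self):
        x = np.random.default_rng(1).uniform(1, 2, size=101)
        assert estimate_alpha(x, x / 2.0, 50, 10) == pytest.approx(2.0)

    def test_matches_direct_sum_oracle_on_offset_sinusoid(self):
        t = np.arange(0, 60, 1 / FS)
        x = 1 + np.sin(2 * np.pi * 0.3 * t)
        xs = smooth(x, 83)
        k = int(np.argmax(xs))
        L = 10
        expected = x[k - L : k + L + 1].sum() / xs[k - L : k + L + 1].sum()
        assert estimate_alpha(x, xs, k, L) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_raises_degenerate(self):
        x = np.zeros(50)
        with pytest.raises(DegenerateSignalError):
            estimate_alpha(np.ones(50), x, 25, 5)

    def test_residual_identities(self):
        x = np.random.default_rng(2).normal(size=64)
        np.testing.assert_allclose(residual(x, x, 1.0), 0.0, atol=1e-15)
        np.testing.assert_allclose(residual(x, np.ones(64), 0.0), x)

    def test_residual_correlates_with_heart_component(self):
        """Removing the breathing estimate raises correlation with the
        heartbeat component."""
        cfg = SimConfig(
            duration_s=60.0,
            resp_rate_per_min=18.0,
            heart_rate_per_min=75.0,
            heart_to_resp_ratio=0.10,
            white_noise_sd=0.0,
            mains_amplitude=0.0,
            seed=8,
        )
        rec, _ = simulate(cfg)
        ch = rec.layout.channel_at_cell(cfg.chest_position)
        win = PeriodWindow(data=rec.channel(ch), period_s=60.0, t_index=0, channel=ch)
        state, params = RateState(), SmoothingParams(fs=FS)
        resp, state, xs = respiratory_rate(win, state, params)
        # the pulse-train component alone: same seed with the heartbeat
        # scaled to zero consumes identical random draws, so the difference
        # isolates the heart contribution exactly
        no_heart = simulate(SimConfig(**{**cfg.__dict__, "heart_to_resp_ratio": 0.0}))[0]
        heart_only = (rec.data[:, ch - 1] - no_heart.data[:, ch - 1])
        heart_only = heart_only - heart_only.mean()
        x = win.values - win.values.mean()
        mean = win.values.mean()
        alpha = estimate_alpha(x, xs - mean, int(resp.peak_indices[0]), 10)
        y = residual(x, xs - mean, alpha)
        corr = lambda a, b: abs(np.corrcoef(a, b)[0, 1])
        assert corr(y, heart_only) > corr(x, heart_only)


class TestFindPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert find_peaks(np.arange(100.0), 5).size == 0

    def test_sinusoid_peak_count(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 0.3 * t)
        assert find_peaks(x, 100).size == 18

    def test_min_distance_keeps_higher_peak(self):
        x = np.zeros(30)
        x[10] = 1.0
        x[12] = 1.5
        peaks = find_peaks(x, 5, prominence_frac=0.01)
        assert list(peaks) == [12]

    def test_flat_series_empty(self):
        assert find_peaks(np.ones(50), 3).size == 0


class TestRates:
    def test_respiratory_rate_noise_free(self, chest_window):
        est, _, _ = respiratory_rate(chest_window, RateState(), SmoothingParams(fs=FS))
        assert est.valid
        assert est.rate_per_min == pytest.approx(18.0, abs=1.0)

    def test_mains_interference_handled(self):
        """Rates are unchanged when mains ripple rides on the signal: at
        fs = 200 a 50 Hz notch removes it before detection."""
        from piezosleep import notch_filter

        base = SimConfig(
            duration_s=60.0,
            fs=200.0,
            white_noise_sd=0.0,
            mains_amplitude=0.0,
            seed=21,
        )
        noisy = SimConfig(**{**base.__dict__, "mains_amplitude": 0.05})
        rates = []
        for cfg, use_notch in ((base, False), (noisy, True)):
            rec, _ = simulate(cfg)
            ch = rec.layout.channel_at_cell(cfg.chest_position)
            series = rec.channel(ch)
            if use_notch:
                series = notch_filter(series, 50.0, 30.0)
            win = PeriodWindow(data=series, period_s=60.0, t_index=0, channel=ch)
            est, _, _ = respiratory_rate(win, RateState(), SmoothingParams(fs=200.0))
            rates.append(est.rate_per_min)
        assert rates[0] == pytest.approx(rates[1], abs=1e-9)

    def test_flat_occupied_signal_invalid_and_state_frozen(self):
        win = make_window(np.full(3000, 1.5), fs=FS)
        state = RateState()
        est, new_state, _ = respiratory_rate(win, state, SmoothingParams(fs=FS))
        assert not est.valid
        assert new_state == state

    def test_heart_rate_noise_free(self, chest_window):
        state, params = RateState(), SmoothingParams(fs=FS)
        resp, state, xs = respiratory_rate(chest_window, state, params)
        heart, _ = heart_rate(
            chest_window, xs, state, params, resp_peaks=resp.peak_indices
        )
        assert heart.valid
        assert heart.rate_per_min == pytest.approx(75.0, abs=2.0)

    def test_heart_smoothing_matches_direct_sum(self, chest_window):
        """The heart-band smoothing pass is the same centered mean with
        half-window w, verified against the direct-sum oracle."""
        state, params = RateState(), SmoothingParams(fs=FS)
        _, state, xs = respiratory_rate(chest_window, state, params)
        y = chest_window.values - 1.2 * xs
        w = half_window(FS, state.h)
        np.testing.assert_allclose(smooth(y, w), smooth_oracle(y, w), atol=1e-12)

    def test_zero_heart_amplitude_invalid(self):
        cfg = SimConfig(
            duration_s=60.0, heart_to_resp_ratio=0.0, mains_amplitude=0.0, seed=5
        )
        rec, _ = simulate(cfg)
        ch = rec.layout.channel_at_cell(cfg.chest_position)
        win = PeriodWindow(data=rec.channel(ch), period_s=60.0, t_index=0, channel=ch)
        state, params = RateState(), SmoothingParams(fs=FS)
        resp, state, xs = respiratory_rate(win, state, params)
        heart, new_state = heart_rate(win, xs, state, params, resp_peaks=resp.peak_indices)
        assert not heart.valid
        assert new_state == state

    def test_dynamic_adaptation_of_window(self):
        """After a window, W equals floor(fs/(4 * previous estimate))."""
        cfg = SimConfig(duration_s=70.0, resp_rate_per_min=24.0, seed=6)
        rec, _ = simulate(cfg)
        ch = rec.layout.channel_at_cell(cfg.chest_position)
        state, params = RateState(), SmoothingParams(fs=FS)
        win1 = PeriodWindow(data=rec.channel(ch), period_s=70.0, t_index=0, channel=ch)
        est1, state, _ = respiratory_rate(win1, state, params)
        est2, _, _ = respiratory_rate(win1, state, params)
        assert est2.window_used == math.floor(FS / (4 * est1.rate_hz))


class TestParameterRecovery:
    def test_median_accuracy_over_50_seeds(self):
        """Dynamic smoothing recovers both rates across the sleep bands:
        60 s periods, breathing 12-30/min, heart 50-100/min at 10-20% of the
        breathing amplitude, mild noise."""
        resp_accs, heart_accs = [], []
        for seed in range(50):
            r = float(np.random.default_rng(seed + 1000).uniform(12, 30))
            h = float(np.random.default_rng(seed + 2000).uniform(50, 100))
            ratio = float(np.random.default_rng(seed + 3000).uniform(0.10, 0.20))
            cfg = SimConfig(
                duration_s=60.0,
                resp_rate_per_min=r,
                heart_rate_per_min=h,
                heart_to_resp_ratio=ratio,
                white_noise_sd=0.01,
                mains_amplitude=0.0,
                seed=seed,
            )
            rec, _ = simulate(cfg)
            ch = rec.layout.channel_at_cell(cfg.chest_position)
            win = PeriodWindow(data=rec.channel(ch), period_s=60.0, t_index=0, channel=ch)
            state, params = RateState(), SmoothingParams(fs=FS)
            resp, state, xs = respiratory_rate(win, state, params)
            heart, _ = heart_rate(win, xs, state, params, resp_peaks=resp.peak_indices)
            resp_accs.append(accuracy(resp.rate_per_min, r) if resp.valid else 0.0)
            heart_accs.append(accuracy(heart.rate_per_min, h) if heart.valid else 0.0)
        assert np.median(resp_accs) >= 95.0
        assert np.median(heart_accs) >= 90.0


class TestAccuracyMetric:
    @pytest.mark.parametrize(
        "measured,true,expected",
        [(17, 18, 94.44), (18, 18, 100.0), (22, 24, 91.67), (21, 20, 95.0)],
    )
    def test_reference_values(self, measured, true, expected):
        assert accuracy(measured, true) == pytest.approx(expected, abs=0.005)

    def test_floored_at_zero(self):
        assert accuracy(50, 10) == 0.0

    def test_nonpositive_true_rejected(self):
        with pytest.raises(ParameterError):
            accuracy(10, 0)
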