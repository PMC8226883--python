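"""Epoching, baseline correction, winsorizing and LBP symbolization."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p300kit.containers import EEGRecording, StimulusEvent
from p300kit.preprocessing import (Trial, WinsorThresholds, apply_winsor,
                                   bandpass, baseline_correct, extract_trial,
                                   fit_winsor, lbp_length,
                                   preprocess_pipeline, resample_to_240,
                                   symbolize_lbp)

FS = 240.0


def _sine(freq, fs=FS, seconds=120.0):
    t = np.arange(int(seconds * fs)) / fs
    return EEGRecording(np.sin(2 * np.pi * freq * t)[None, :], fs)


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))


def _interior(signal, fs=FS, margin_s=10.0):
    m = int(margin_s * fs)
    return signal[:, m:-m]


class TestBandpass:
    # the 0.1 Hz high-pass edge has a multi-second impulse response, so
    # band behaviour is judged away from the filtfilt startup edges
    def test_stopband_rejects_50hz(self):
        rec = _sine(50.0)
        out = bandpass(rec)
        assert _rms(_interior(out.signal)) < 0.05 * _rms(rec.signal)

    def test_passband_preserves_5hz(self):
        rec = _sine(5.0)
        out = bandpass(rec)
        assert abs(_rms(_interior(out.signal)) - _rms(rec.signal)) \
            < 0.10 * _rms(rec.signal)

    def test_dc_attenuated(self):
        rec = EEGRecording(np.full((1, int(60 * FS)), 7.0), FS)
        out = bandpass(rec)
        # high-pass edge at 0.1 Hz drains the constant over a long window
        assert _rms(out.signal) < 0.2 * 7.0

    def test_invalid_band(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(_sine(5.0), lo=30, hi=20)


class TestResample:
    def test_constant_preserved(self):
        rec = EEGRecording(np.full((2, 250), 3.5), 250.0)
        out = resample_to_240(rec)
        assert out.fs == 240.0
        assert out.signal.shape == (2, 240)
        assert np.allclose(out.signal, 3.5)

    def test_sinusoid_against_analytic_resampling(self):
        t = np.arange(2500) / 250.0
        rec = EEGRecording(np.sin(2 * np.pi * 2.0 * t)[None, :], 250.0)
        out = resample_to_240(rec)
        ref = np.sin(2 * np.pi * 2.0 * np.arange(out.signal.shape[1]) / 240.0)
        mid = slice(100, -100)  # ignore filter edge effects
        r = np.corrcoef(out.signal[0][mid], ref[mid])[0, 1]
        assert r >= 0.999

    def test_identity_at_240(self):
        rec = EEGRecording(np.arange(480, dtype=float)[None, :], 240.0)
        assert resample_to_240(rec) is rec

    def test_other_rates_rejected(self):
        with pytest.raises(ValueError, match="250"):
            resample_to_240(EEGRecording(np.zeros((1, 100)), 200.0))


class TestExtractTrial:
    def test_default_window_is_168_samples(self):
        rec = EEGRecording(np.arange(500, dtype=float)[None, :], FS)
        trial = extract_trial(rec, StimulusEvent(0, 1, True))
        assert trial.n_samples == 168
        # samples 24..191 of the ramp
        assert trial.window[0, 0] == 24
        assert trial.window[0, -1] == 191

    def test_ramp_restriction(self):
        rec = EEGRecording(np.arange(1000, dtype=float)[None, :], FS)
        trial = extract_trial(rec, StimulusEvent(100, 2, False))
        assert np.array_equal(trial.window[0], np.arange(124, 292, dtype=float))

    def test_out_of_bounds_identifies_event(self):
        rec = EEGRecording(np.zeros((1, 300)), FS)
        with pytest.raises(ValueError, match="sample 200"):
            extract_trial(rec, StimulusEvent(200, 3, False))


class TestBaseline:
    def test_constant_becomes_zero(self):
        out = baseline_correct(Trial(np.full((2, 168), 4.2)))
        assert np.allclose(out.window, 0.0)

    def test_step_offset(self):
        w = np.concatenate([np.full(12, 10.0), np.full(156, 12.0)])[None, :]
        out = baseline_correct(Trial(w))
        assert np.allclose(out.window[0, :12], 0.0)
        assert np.allclose(out.window[0, 12:], 2.0)

    def test_first_samples_zero_mean(self, rng):
        trial = Trial(rng.normal(size=(3, 168)))
        out = baseline_correct(trial)
        assert np.allclose(out.window[:, :12].mean(axis=1), 0.0, atol=1e-12)

    def test_invalid_length(self):
        with pytest.raises(ValueError, match="baseline_len"):
            baseline_correct(Trial(np.zeros((1, 168))), baseline_len=0)


class TestWinsor:
    def test_uniform_grid_matches_interpolation_oracle(self):
        values = np.arange(1.0, 1001.0)  # 1..1000 per channel
        trials = values.reshape(1, 1, -1)

        def percentile_oracle(sorted_vals, q):
            # linear interpolation between order statistics
            h = (len(sorted_vals) - 1) * q / 100.0
            lo = int(np.floor(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[lo + 1] - sorted_vals[lo])

        thr = fit_winsor(trials)
        assert thr.p_low[0] == pytest.approx(percentile_oracle(values, 1))
        assert thr.p_high[0] == pytest.approx(percentile_oracle(values, 99))
        assert thr.p_low[0] == pytest.approx(10.99)
        assert thr.p_high[0] == pytest.approx(990.01)

    def test_constant_channel(self):
        thr = fit_winsor(np.full((2, 1, 100), 5.0))
        assert thr.p_low[0] == thr.p_high[0] == 5.0

    def test_symmetric_data(self, rng):
        x = rng.normal(size=(10, 1, 200))
        sym = np.concatenate([x, -x], axis=2)
        thr = fit_winsor(sym)
        assert thr.p_low[0] == pytest.approx(-thr.p_high[0])

    def test_thresholds_bracket_98_percent(self, rng):
        data = rng.normal(size=(20, 3, 168))
        thr = fit_winsor(data)
        per_ch = data.transpose(1, 0, 2).reshape(3, -1)
        inside = (per_ch >= thr.p_low[:, None]) & (per_ch <= thr.p_high[:, None])
        # interpolated percentiles leave at most one extra point per tail
        n = per_ch.shape[1]
        assert inside.mean(axis=1).min() >= 0.98 - 2.0 / n

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_winsor([])

    def test_small_set_warns(self):
        with pytest.warns(UserWarning, match="100"):
            fit_winsor(np.zeros((1, 1, 50)))

    def test_apply_clips_only_outsiders_and_is_idempotent(self, rng):
        thr = WinsorThresholds([-1.0], [1.0])
        w = rng.uniform(-3, 3, size=(1, 168))
        once = apply_winsor(Trial(w), thr)
        inside = (w >= -1) & (w <= 1)
        assert np.array_equal(once.window[inside], w[inside])
        assert once.window.min() >= -1 and once.window.max() <= 1
        assert set(np.unique(once.window[~inside])) <= {-1.0, 1.0}
        twice = apply_winsor(once, thr)
        assert np.array_equal(once.window, twice.window)

    def test_channel_mismatch(self):
        with pytest.raises(ValueError, match="channels"):
            apply_winsor(Trial(np.zeros((3, 168))), WinsorThresholds([0.0], [1.0]))


class TestSymbolize:
    def test_increasing_ramp_all_eight(self):
        trial = Trial(np.arange(168, dtype=float)[None, :])
        s = symbolize_lbp(trial)
        assert s.shape == (54, 1)
        assert np.all(s == 8)

    def test_constant_and_decreasing_all_zero(self):
        assert np.all(symbolize_lbp(Trial(np.zeros((1, 168)))) == 0)
        assert np.all(symbolize_lbp(Trial(-np.arange(168.0)[None, :])) == 0)

    def test_alternating_pattern_hand_enumeration(self):
        # a,b,a,b,... with a<b: onset on a sees 4 larger samples of the
        # following 8; onset on b sees none
        w = np.tile([0.0, 1.0], 84)[None, :]
        s = symbolize_lbp(Trial(w))[:, 0]
        onsets = np.arange(54) * 3
        expected = np.where(onsets % 2 == 0, 4, 0)
        assert np.array_equal(s, expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            symbolize_lbp(Trial(np.zeros((1, 8))))

    @given(T=st.integers(min_value=100, max_value=300))
    @settings(max_examples=40, deadline=None)
    def test_length_formula(self, T):
        rng = np.random.default_rng(T)
        s = symbolize_lbp(Trial(rng.normal(size=(2, T))))
        assert s.shape == ((T - 8 - 1) // 3 + 1, 2)
        assert s.min() >= 0 and s.max() <= 8

    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           offset=st.floats(min_value=-50, max_value=50),
           cube=st.booleans())
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, scale, offset, cube):
        rng = np.random.default_rng(99)
        w = rng.normal(size=(2, 168))
        base = symbolize_lbp(Trial(w))
        v = scale * w + offset
        if cube:
            v = v**3  # strictly increasing
        assert np.array_equal(base, symbolize_lbp(Trial(v)))


class TestPipeline:
    def test_counts_and_shape(self, four_choice_session, four_choice_symbols):
        _, schedule, _ = four_choice_session
        sts = four_choice_symbols
        assert sts.symbols.shape == (len(schedule), 54, 6)
        assert sts.symbols.min() >= 0 and sts.symbols.max() <= 8

    def test_offset_invariance(self, four_choice_session):
        recording, schedule, _ = four_choice_session
        sts = preprocess_pipeline(recording, schedule)
        shifted = EEGRecording(recording.signal + 500.0, recording.fs)
        sts2 = preprocess_pipeline(shifted, schedule)
        assert np.array_equal(sts.symbols, sts2.symbols)

    def test_positive_scaling_invariance_with_refit(self, four_choice_session):
        recording, schedule, _ = four_choice_session
        sts = preprocess_pipeline(recording, schedule)
        scaled = EEGRecording(recording.signal * 3.7, recording.fs)
        sts2 = preprocess_pipeline(scaled, schedule)  # thresholds refit
        assert np.array_equal(sts.symbols, sts2.symbols)

    def test_determinism(self, four_choice_session):
        recording, schedule, _ = four_choice_session
        a = preprocess_pipeline(recording, schedule)
        b = preprocess_pipeline(recording, schedule)
        assert np.array_equal(a.symbols, b.symbols)

    def test_thresholds_reused_on_test_data(self, four_choice_session):
        recording, schedule, _ = four_choice_session
        train = preprocess_pipeline(recording, schedule)
        test = preprocess_pipeline(recording, schedule, train.thresholds)
        assert np.array_equal(train.symbols, test.symbols)
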