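"""Envelopes, onset detection, DTW alignment and warping-curve arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynaface import temporal
from dynaface.media_io import AudioSignal
from dynaface.temporal import Envelope, WarpCurve


def _bump_envelope(times, rate=4800.0, duration=1.0, sigma=0.02):
    t = np.arange(int(duration * rate)) / rate
    env = np.zeros_like(t)
    for t0 in times:
        env += np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return Envelope(env, rate=rate)


class TestHilbertEnvelope:
    def test_sine_amplitude_recovered(self):
        rate = 48000.0
        t = np.arange(int(rate)) / rate
        audio = AudioSignal(0.6 * np.sin(2 * np.pi * 440 * t), rate)
        env = temporal.hilbert_envelope(audio)
        mid = env.values[2000:-2000]
        assert np.abs(mid - 0.6).max() / 0.6 < 0.02

    def test_zero_and_scaling(self):
        audio = AudioSignal(np.zeros(1000))
        assert np.allclose(temporal.hilbert_envelope(audio).values, 0.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=4096)
        e1 = temporal.hilbert_envelope(AudioSignal(x)).values
        e2 = temporal.hilbert_envelope(AudioSignal(-2.5 * x)).values
        assert np.allclose(e2, 2.5 * e1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            temporal.hilbert_envelope(AudioSignal(np.zeros(32)))


class TestOnsetDetection:
    def test_step_rise_backs_off_80ms_and_rounds(self):
        rate = 4800.0
        env = np.zeros(int(2 * rate))
        env[int(1.0 * rate):] = 1.0
        onset = temporal.detect_onset(Envelope(env, rate), fps=25.0)
        assert onset == pytest.approx(0.920)

    def test_silent_clip_errors(self):
        with pytest.raises(RuntimeError):
            temporal.detect_onset(Envelope(np.zeros(4800), 4800.0))

    def test_override_wins(self):
        env = Envelope(np.zeros(4800), 4800.0)
        assert temporal.detect_onset(env, override=0.6) == 0.6


class TestDecimation:
    def test_rate_division(self):
        env = Envelope(np.random.default_rng(0).uniform(0, 1, 48000), 48000.0)
        out = temporal.decimate_envelope(env, 10)
        assert out.rate == 4800.0
        assert out.values.size == 4800

    def test_dc_preserved(self):
        env = Envelope(np.full(48000, 0.42), 48000.0)
        out = temporal.decimate_envelope(env, 10)
        assert np.abs(out.values - 0.42).max() < 0.42 * 0.01

    def test_low_frequency_waveform_preserved(self):
        rate = 48000.0
        t = np.arange(int(rate)) / rate
        env = Envelope(1.0 + 0.5 * np.sin(2 * np.pi * 100 * t), rate)
        out = temporal.decimate_envelope(env, 10)
        t2 = np.arange(out.values.size) / out.rate
        expect = 1.0 + 0.5 * np.sin(2 * np.pi * 100 * t2)
        inner = slice(50, -50)
        corr = np.corrcoef(out.values[inner], expect[inner])[0, 1]
        assert corr > 0.999

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            temporal.decimate_envelope(Envelope(np.ones(100), 48000.0), 0)


class TestAlignment:
    def test_identical_envelopes_give_identity_curves(self):
        env = _bump_envelope([0.2, 0.5, 0.8])
        curves, ref, info = temporal.align_envelopes(
            [env, Envelope(env.values.copy(), env.rate)], n_iterations=2)
        for c in curves:
            assert np.abs(c.mapping - np.arange(len(c))).max() <= 1.0

    def test_known_warp_recovered(self):
        """A clip that is the reference warped by a known monotone g must
        yield a curve approximating g."""
        rate = 4800.0
        ref = _bump_envelope([0.15, 0.4, 0.65, 0.9], rate=rate, duration=1.1)
        t_ref = np.arange(ref.values.size) / rate
        # g: reference time -> clip time, slope varying within [1.0, 1.1]
        g = 1.05 * t_ref + 0.0175 * np.sin(np.pi * t_ref / 1.1)
        t_clip = np.arange(int(g[-1] * rate)) / rate
        clip_vals = np.interp(np.interp(t_clip, g, t_ref), t_ref, ref.values)
        clip = Envelope(clip_vals, rate)
        ident = Envelope(ref.values.copy(), rate)
        curves, _, info = temporal.align_envelopes([ref, ident, clip],
                                                   n_iterations=3)
        # The reference timeline stays anchored to an identity-warped clip,
        # so the recovered curve estimates g directly.
        w_s = curves[2].mapping / rate
        expect = np.interp(np.arange(w_s.size) / rate, t_ref, g)
        assert np.median(np.abs(w_s - expect)) * rate <= 2.0

    def test_objective_non_increasing(self, fitted):
        _, report = fitted
        hist = report["alignment_objective"]
        assert len(hist) == 3
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_all_curves_share_reference_length(self, fitted):
        model, report = fitted
        assert len({len(c) for c in model.curves}) == 1
        assert all(a.shape[0] == model.t_ref for a in model.aligned_scores)

    def test_too_few_envelopes_rejected(self):
        with pytest.raises(ValueError):
            temporal.align_envelopes([_bump_envelope([0.5])])

    def test_flat_envelope_warns_identity(self):
        env = _bump_envelope([0.3, 0.6])
        flat = Envelope(np.full_like(env.values, 0.2), env.rate)
        with pytest.warns(UserWarning):
            curves, _, _ = temporal.align_envelopes([env, flat], 1)


class TestVideoCurves:
    def test_lengths_and_prepended_gradient(self):
        rate, fps = 4800.0, 25.0
        n = 2000
        curve = WarpCurve(2.0 * np.arange(n), rate=rate)  # slope 2
        video = temporal.audio_to_video_curve(curve, fps=fps, pre_frames=4)
        n_interp = int(np.floor((n - 1) / (rate / fps))) + 1
        assert len(video) == n_interp + 4
        grads = np.diff(video.mapping)
        assert np.allclose(grads[:4], 1.0)
        assert np.allclose(grads[6:-1], 2.0, atol=1e-6)

    def test_identity_curve_maps_frames_to_frames(self):
        curve = WarpCurve(np.arange(1920.0), rate=4800.0)
        video = temporal.audio_to_video_curve(curve, pre_frames=0)
        assert np.allclose(video.mapping, np.arange(len(video)))

    def test_bad_fps_rejected(self):
        with pytest.raises(ValueError):
            temporal.audio_to_video_curve(WarpCurve(np.arange(100.0), 4800.0),
                                          fps=0)


class TestTimeseriesWarping:
    def test_identity_and_constant(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(20, 4))
        ident = WarpCurve(np.arange(20.0), rate=25.0)
        assert np.allclose(temporal.warp_timeseries(scores, ident), scores)
        const = np.tile([1.0, 2.0], (20, 1))
        curve = WarpCurve(np.linspace(0, 19, 20) ** 1.2 / 19 ** 0.2, rate=25.0)
        assert np.allclose(temporal.warp_timeseries(const, curve), const)

    def test_warp_then_unwarp_recovers_smooth_series(self):
        t = np.arange(40)
        scores = np.stack([np.sin(2 * np.pi * t / 40),
                           np.cos(2 * np.pi * t / 40)], axis=1)
        mapping = np.linspace(0, 39, 48)
        curve = WarpCurve(mapping, rate=25.0)
        aligned = temporal.warp_timeseries(scores, curve)
        back = temporal.unwarp_timeseries(aligned, curve)
        n = min(back.shape[0], scores.shape[0])
        for k in range(2):
            corr = np.corrcoef(back[:n, k], scores[:n, k])[0, 1]
            assert corr > 0.99

    def test_out_of_range_clamped_with_warning(self):
        scores = np.random.default_rng(2).normal(size=(10, 2))
        curve = WarpCurve(np.linspace(0, 15, 12), rate=25.0)
        with pytest.warns(UserWarning):
            out = temporal.warp_timeseries(scores, curve)
        assert out.shape == (12, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            temporal.warp_timeseries(np.zeros((0, 3)),
                                     WarpCurve(np.arange(5.0), 25.0))


class TestCurveGradients:
    def test_identity_gradients_are_one(self):
        curve = WarpCurve(np.arange(10.0), rate=25.0)
        assert np.allclose(temporal.curve_gradients(curve), 1.0)

    def test_negative_gradients_clipped_with_warning(self):
        grads = np.array([1.0, -0.5, 1.0, 1.0])
        with pytest.warns(UserWarning):
            curve = temporal.gradients_to_curve(grads)
        assert np.all(np.diff(curve.mapping) >= 1e-3 - 1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 999), n=st.integers(3, 60),
           anchor=st.floats(-5, 20))
    def test_roundtrip_exact(self, seed, n, anchor):
        rng = np.random.default_rng(seed)
        mapping = anchor + np.cumsum(rng.uniform(0.0, 2.0, n))
        curve = WarpCurve(mapping, rate=25.0)
        grads = temporal.curve_gradients(curve)
        back = temporal.gradients_to_curve(grads, anchor=mapping[0], rate=25.0)
        assert np.abs(back.mapping - mapping).max() < 1e-10
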