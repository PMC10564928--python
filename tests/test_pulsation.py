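
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onhpulse.imgproc import ImageSequence
from onhpulse.pulsation import (
    IntensityWaveform,
    detrend_linear,
    extract_waveform,
    fit_sinusoid,
    moving_average_gain,
    qc_exclude,
    smooth_and_trim,
    to_metrics,
)


def wf(t, y, **kw):
    return IntensityWaveform(t=np.asarray(t, float), y_raw=np.asarray(y, float),
                             **kw)


def fitted(t, y):
    return fit_sinusoid(smooth_and_trim(detrend_linear(wf(t, y))))


def fitted_no_detrend(t, y):
    return fit_sinusoid(smooth_and_trim(wf(t, y)))


def ols_line_brute(t, y):
    """Independent least-squares line via the normal-equation formulas."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    slope = (tc * (y - y.mean())).sum() / (tc**2).sum()
    return slope, y.mean() - slope * t.mean()


class TestExtractWaveform:
    def test_constant_frames(self):
        seq = ImageSequence(frames=np.full((5, 8, 8), 100.0),
                            timestamps=np.arange(5) / 24.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        w = extract_waveform(seq, mask)
        assert (w.y_raw == 100.0).all()

    def test_single_pixel_mask_is_pixel_trace(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(6, 5, 5))
        seq = ImageSequence(frames=frames, timestamps=np.arange(6.0))
        mask = np.zeros((5, 5), dtype=bool)
        mask[3, 1] = True
        w = extract_waveform(seq, mask)
        assert np.allclose(w.y_raw, frames[:, 3, 1])

    def test_empty_mask_rejected(self):
        seq = ImageSequence(frames=np.zeros((3, 4, 4)),
                            timestamps=np.arange(3.0))
        with pytest.raises(ValueError, match="empty"):
            extract_waveform(seq, np.zeros((4, 4), dtype=bool))

    def test_phantom_vessel_waveform_matches_sidecar(self, noiseless_video):
        vid = noiseless_video
        seq = vid.seq
        w = extract_waveform(seq, vid.vessel_mask, roi_name="RV")
        gt = vid.truth
        t = seq.timestamps
        expected = w.y_raw[0] + gt.waveform(t) - gt.waveform(0.0) \
            + gt.drift_slope * t
        assert np.abs(w.y_raw - expected).max() < 1e-9


class TestDetrend:
    def test_pure_ramp_becomes_flat_at_mean(self):
        t = np.linspace(0.0, 3.0, 72)
        y = 5.0 * t + 2.0
        w = detrend_linear(wf(t, y))
        assert np.allclose(w.y_detrended, y.mean())

    def test_removes_exactly_the_brute_force_ols_line(self):
        t = np.arange(72) / 24.0
        y = np.sin(2 * np.pi * 1.0 * t + 0.3)
        slope, intercept = ols_line_brute(t, y)
        w = detrend_linear(wf(t, y))
        assert np.allclose(w.y_detrended,
                           y - (slope * t + intercept) + y.mean(), atol=1e-12)

    def test_recovers_drift_slope_on_phantom_mix(self):
        # the fitted slope is the injected drift plus the sinusoid's own
        # small OLS slope (computed by the independent formula)
        t = np.arange(72) / 24.0
        sinus = 2.0 * np.sin(2 * np.pi * 1.0 * t + 0.7)
        y = sinus + 3.0 * t + 50.0
        slope, _ = np.polyfit(t, y, 1)
        s_sin, _ = ols_line_brute(t, sinus)
        assert slope == pytest.approx(3.0 + s_sin, abs=1e-9)
        w = detrend_linear(wf(t, y))
        resid = w.y_detrended - w.y_detrended.mean()
        assert np.allclose(resid, sinus - (s_sin * t + sinus.mean()
                                           - s_sin * t.mean()), atol=1e-9)

    def test_mean_retained(self):
        t = np.arange(10.0)
        y = 0.5 * t + 7.0
        w = detrend_linear(wf(t, y))
        assert w.y_detrended.mean() == pytest.approx(y.mean())


class TestSmoothing:
    def test_72_samples_yield_68_points(self, waveform_7224):
        y = np.sin(waveform_7224)
        w = smooth_and_trim(wf(waveform_7224, y))
        assert len(w.y_smoothed) == 68
        assert len(w.t_smoothed) == 68

    def test_constant_preserved(self):
        w = smooth_and_trim(wf(np.arange(9.0), np.full(9, 4.2)))
        assert np.allclose(w.y_smoothed, 4.2)

    def test_small_worked_example(self):
        w = smooth_and_trim(wf(np.arange(7.0), [1, 2, 3, 4, 5, 6, 7]))
        assert np.allclose(w.y_smoothed, [3.0, 4.0, 5.0])
        assert np.allclose(w.t_smoothed, [2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_trim(wf(np.arange(4.0), np.arange(4.0)))

    @given(n=st.integers(min_value=5, max_value=300))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_output_always_four_shorter(self, n):
        rng = np.random.default_rng(n)
        w = smooth_and_trim(wf(np.arange(n, dtype=float), rng.normal(size=n)))
        assert len(w.y_smoothed) == n - 4

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_running_mean_never_increases_variance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=32)
        w = smooth_and_trim(wf(np.arange(32.0), y))
        assert w.y_smoothed.var() <= y.var() + 1e-12


class TestFitSinusoid:
    def test_noiseless_sinusoid_recovered_with_known_attenuation(
            self, waveform_7224):
        t = waveform_7224
        B_true = 2 * np.pi * 1.2
        y = 2.0 * np.sin(B_true * t + 0.5) + 10.0
        fit = fitted_no_detrend(t, y)
        gain = moving_average_gain(B_true, 1 / 24.0)
        assert fit.status == "ok"
        assert fit.B == pytest.approx(B_true, rel=1e-6)
        assert fit.A == pytest.approx(2.0 * gain, rel=1e-6)
        assert fit.D == pytest.approx(10.0, abs=1e-6)
        assert fit.r_squared >= 0.999

    def test_constant_input_degenerate_and_excluded(self, waveform_7224):
        fit = fitted(waveform_7224, np.full(72, 5.0))
        assert fit.status == "degenerate"
        assert np.isnan(fit.r_squared)
        metrics = to_metrics(fit)
        assert metrics.excluded

    def test_canonical_form_invariants(self, waveform_7224):
        t = waveform_7224
        rng = np.random.default_rng(11)
        for _ in range(5):
            A = rng.uniform(0.5, 3.0)
            B = 2 * np.pi * rng.uniform(0.9, 1.5)
            C = rng.uniform(-6.0, 6.0)
            y = A * np.sin(B * t + C) + 20.0
            fit = fitted(t, y)
            assert fit.A >= 0 and fit.B > 0
            assert 0.0 <= fit.C < 2 * np.pi

    def test_negative_amplitude_canonicalization_preserves_model(self):
        from onhpulse.pulsation import _canonicalize

        t = np.linspace(0, 3, 68)
        for A, B, C in [(-2.0, 7.0, 0.3), (2.0, -7.0, 0.3), (-2.0, -7.0, 5.0)]:
            Ac, Bc, Cc = _canonicalize(A, B, C)
            assert Ac >= 0 and Bc > 0 and 0 <= Cc < 2 * np.pi
            assert np.allclose(A * np.sin(B * t + C),
                               Ac * np.sin(Bc * t + Cc), atol=1e-9)

    def test_requires_smoothed_input(self, waveform_7224):
        with pytest.raises(ValueError, match="smoothed"):
            fit_sinusoid(wf(waveform_7224, np.sin(waveform_7224)))

    def test_affine_offset_leaves_pa_pf_unchanged(self, waveform_7224):
        t = waveform_7224
        y = 1.5 * np.sin(2 * np.pi * 1.1 * t + 1.0) + 30.0
        base = fitted(t, y)
        shifted = fitted(t, y + 4.0 * t - 17.0)
        assert shifted.A == pytest.approx(base.A, abs=1e-6)
        assert shifted.B == pytest.approx(base.B, abs=1e-6)

    def test_whole_sample_time_shift_changes_only_phase(self, waveform_7224):
        t = waveform_7224
        B = 2 * np.pi * 1.2

        def model(tt):
            return 2.0 * np.sin(B * tt + 0.5) + 10.0

        base = fitted_no_detrend(t, model(t))
        shifted = fitted_no_detrend(t, model(t + 5.0 / 24.0))
        assert shifted.A == pytest.approx(base.A, abs=1e-6)
        assert shifted.B == pytest.approx(base.B, abs=1e-6)
        assert abs((shifted.C - base.C) % (2 * np.pi)) > 1e-3


class TestMetricsAndQc:
    @pytest.mark.parametrize("B, pf", [
        (2 * np.pi, 60.0),
        (2 * np.pi * 70.0 / 60.0, 70.0),
    ])
    def test_angular_frequency_to_bpm(self, B, pf):
        from onhpulse.pulsation import SinusoidFit

        fit = SinusoidFit(A=1.83, B=B, C=0.0, D=0.0, r_squared=0.9)
        m = to_metrics(fit)
        assert m.PF == pytest.approx(pf)
        assert m.PA == pytest.approx(1.83)

    def test_fixed_threshold_flags(self):
        flags = qc_exclude(np.array([0.1, 0.3, 0.5]), mode="fixed", value=0.23)
        assert flags.tolist() == [True, False, False]

    def test_fixed_zero_excludes_nothing(self):
        flags = qc_exclude(np.array([0.0, 0.4, 0.9]), mode="fixed", value=0.0)
        assert not flags.any()

    def test_percentile_matches_brute_force(self):
        vals = np.arange(0.05, 1.0, 0.1)  # 0.05, 0.15, ..., 0.95
        flags = qc_exclude(vals, mode="percentile", value=10.0)
        # linear-interpolation 10th percentile of these ten values is 0.14
        cutoff = np.percentile(vals, 10.0)
        assert flags.tolist() == (vals < cutoff).tolist()
        assert flags.sum() == 1 and flags[0]

    def test_subject_excluded_if_either_roi_poor(self):
        r2 = np.array([[0.8, 0.1], [0.6, 0.7], [0.1, 0.9]])
        flags = qc_exclude(r2, mode="fixed", value=0.23)
        assert flags.tolist() == [True, False, True]

    def test_nan_always_excluded(self):
        flags = qc_exclude(np.array([np.nan, 0.5]), mode="fixed", value=0.23)
        assert flags.tolist() == [True, False]


class TestFullWaveformRecovery:
    def test_pipeline_recovery_on_phantom(self, jittered_video, registered):
        from onhpulse.pulsation import analyze_sequence

        vid = jittered_video
        res = analyze_sequence(registered.registered,
                               {"RV": vid.vessel_mask})
        m = res["RV"]["metrics"]
        gt = vid.truth
        gain = moving_average_gain(2 * np.pi * gt.f_true / 60.0, 1 / 24.0)
        assert m.PF == pytest.approx(gt.f_true, abs=1.0)
        assert m.PA == pytest.approx(gt.A_true * gain, rel=0.10)
        assert m.r_squared > 0.9
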