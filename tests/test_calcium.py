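"""ROI extraction, trace corrections, noise, and transient quantification."""

import math

import numpy as np
import pytest

from mechanoca import (
    FluorescenceTrace,
    ImageStack,
    RoiSpec,
    align_timebases,
    characterize_transient,
    correct_bleaching,
    correct_reflection_artifact,
    detect_transients,
    estimate_noise,
    extract_roi_trace,
    flag_spontaneous,
    measure_series_amplitudes,
    normalize_baseline,
    quantify_transients,
)
from mechanoca.calcium import CORRECTED, NORMALIZED
from mechanoca.errors import (
    AlignmentUndefinedError,
    DegenerateTraceError,
    GeometryError,
    PreconditionError,
)

FRAME = 0.345


def make_trace(intensity, state=CORRECTED, noise=None, dt=FRAME):
    intensity = np.asarray(intensity, dtype=float)
    return FluorescenceTrace(
        time=np.arange(intensity.size) * dt,
        intensity=intensity,
        state=state,
        noise=noise,
    )


def gaussian_trace(amp=1.0, sigma=0.5, center=10.0, n=60, dt=FRAME, basal=1.0):
    t = np.arange(n) * dt
    return make_trace(basal + amp * np.exp(-((t - center) ** 2) / (2 * sigma**2)), dt=dt)


# ---------------------------------------------------------------------------
# ROI extraction


class TestRoiExtraction:
    def test_uniform_stack_gives_constant_trace(self):
        stack = ImageStack(
            frames=np.full((5, 20, 20), 7.5),
            frame_times=np.arange(5) * FRAME,
            pixel_size=0.5,
        )
        roi = RoiSpec("circle", center=(10, 10), diameter=5.0)
        trace = extract_roi_trace(stack, roi)
        np.testing.assert_allclose(trace.intensity, 7.5)

    def test_matches_exhaustive_pixel_loop(self, rng):
        frames = rng.random((6, 24, 24))
        stack = ImageStack(frames, np.arange(6) * FRAME, pixel_size=0.5)
        roi = RoiSpec("circle", center=(11.3, 12.1), diameter=5.0)
        trace = extract_roi_trace(stack, roi)
        r_px = 5.0 / 2 / 0.5
        for f in range(6):
            acc, count = 0.0, 0
            for r in range(24):
                for c in range(24):
                    if (r - 11.3) ** 2 + (c - 12.1) ** 2 <= r_px**2:
                        acc += frames[f, r, c]
                        count += 1
            assert trace.intensity[f] == pytest.approx(acc / count, rel=1e-12)

    def test_corner_roi_rejected(self):
        stack = ImageStack(np.zeros((3, 16, 16)), np.arange(3) * FRAME, 0.5)
        with pytest.raises(GeometryError):
            extract_roi_trace(stack, RoiSpec("circle", center=(0, 0), diameter=5.0))

    def test_ellipse_mask(self):
        stack = ImageStack(np.ones((3, 30, 30)), np.arange(3) * FRAME, 0.5)
        roi = RoiSpec("ellipse", center=(15, 15), axes=(10.0, 6.0))
        trace = extract_roi_trace(stack, roi)
        np.testing.assert_allclose(trace.intensity, 1.0)


# ---------------------------------------------------------------------------
# Normalization


class TestNormalizeBaseline:
    def test_constant_trace_becomes_ones(self):
        trace = make_trace(np.full(30, 123.0), state="raw")
        out = normalize_baseline(trace)
        np.testing.assert_allclose(out.intensity, 1.0)
        assert out.state == NORMALIZED

    def test_relative_levels(self):
        y = np.full(30, 50.0)
        y[20:] = 100.0
        out = normalize_baseline(make_trace(y, state="raw"))
        assert out.intensity[25] == pytest.approx(2.0)

    def test_inversion_oracle(self, rng):
        y = rng.uniform(50, 150, 40)
        trace = make_trace(y, state="raw")
        b = y[:10].mean()
        out = normalize_baseline(trace)
        np.testing.assert_allclose(out.intensity * b, y, rtol=1e-12)

    def test_renormalization_is_idempotent(self, rng):
        y = rng.uniform(50, 150, 40)
        once = normalize_baseline(make_trace(y, state="raw"))
        twice = normalize_baseline(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, rtol=1e-12)

    def test_degenerate_baseline(self):
        with pytest.raises(DegenerateTraceError):
            normalize_baseline(make_trace(np.zeros(30), state="raw"))


# ---------------------------------------------------------------------------
# Bleaching correction


class TestBleachingCorrection:
    def test_pure_exponential_flattens_to_one(self):
        t = np.arange(100) * FRAME
        trace = FluorescenceTrace(t, np.exp(-0.01 * t), state=NORMALIZED)
        out = correct_bleaching(trace)
        np.testing.assert_allclose(out.intensity, 1.0, atol=1e-6)

    def test_no_decay_is_identity(self):
        trace = make_trace(np.ones(60), state=NORMALIZED)
        out = correct_bleaching(trace)
        np.testing.assert_allclose(out.intensity, trace.intensity, atol=1e-12)

    def test_transient_amplitude_preserved_within_5_percent(self):
        t = np.arange(120) * FRAME
        amp = 0.8
        pulse = amp * np.exp(-((t - 20.0) ** 2) / (2 * 1.5**2))
        trace = FluorescenceTrace(t, np.exp(-0.008 * t) * (1 + pulse), state=NORMALIZED)
        out = correct_bleaching(trace)
        assert out.intensity.max() - 1 == pytest.approx(amp, rel=0.05)

    def test_anchor_mask_grows_over_quiescent_frames(self):
        t = np.arange(120) * FRAME
        pulse = 1.0 * np.exp(-((t - 15.0) ** 2) / (2 * 1.0**2))
        trace = FluorescenceTrace(t, np.exp(-0.01 * t) * (1 + pulse), state=NORMALIZED)
        out = correct_bleaching(trace, anchor=t < 10.0)
        # far from the pulse the output is flat at 1
        late = t > 30.0
        np.testing.assert_allclose(out.intensity[late], 1.0, atol=1e-3)

    def test_requires_normalized_state(self):
        with pytest.raises(PreconditionError):
            correct_bleaching(make_trace(np.ones(30), state="raw"))


# ---------------------------------------------------------------------------
# Reflection artifact


def _deflection_record(n=80, start=30, width=12, dmax=50.0, dt=FRAME):
    t = np.arange(n) * dt
    d = np.zeros(n)
    ramp = np.linspace(0, dmax, width // 2)
    d[start : start + width // 2] = ramp
    d[start + width // 2 : start + width] = ramp[::-1]
    return t, d


class TestReflectionArtifact:
    def test_pure_artifact_removed_to_constant(self):
        t, d = _deflection_record()
        for gain in (0.004, -0.002):
            trace = FluorescenceTrace(t, 1.0 + gain * d, state=NORMALIZED)
            out = correct_reflection_artifact(trace, t, d)
            np.testing.assert_allclose(out.intensity, 1.0, atol=1e-9)
            # post-condition: no deflection-correlated component remains
            # (residual is numerically zero here, which satisfies it)
            resid = out.intensity - 1.0
            if resid.std() > 1e-9:
                assert abs(np.corrcoef(resid, d)[0, 1]) < 0.05

    def test_zero_deflection_is_identity(self):
        t, d = _deflection_record(dmax=0.0)
        trace = FluorescenceTrace(t, 1.0 + 0.1 * np.sin(t), state=NORMALIZED)
        out = correct_reflection_artifact(trace, t, d)
        np.testing.assert_allclose(out.intensity, trace.intensity)

    def test_transient_amplitude_preserved_within_5_percent(self):
        # local-response geometry: the calcium signal rises over the
        # contact window, peaks at maximum deflection, and holds near its
        # peak briefly after release before decaying
        t, d = _deflection_record(start=30, width=12)
        onset, peak = t[30], t[36]
        amp = 1.0
        rise = np.clip((t - onset) / (peak - onset), 0, 1)
        hold_until = peak + 2.5
        decay = np.where(t > hold_until, np.exp(-(t - hold_until) / 3.0), 1.0)
        pulse = amp * rise * decay
        trace = FluorescenceTrace(t, 1.0 + pulse + 0.003 * d, state=NORMALIZED)
        out = correct_reflection_artifact(trace, t, d)
        assert out.intensity.max() - 1 == pytest.approx(amp, rel=0.05)

    def test_short_deflection_record_is_a_coverage_error(self):
        t, d = _deflection_record()
        trace = FluorescenceTrace(t, np.ones_like(t), state=NORMALIZED)
        from mechanoca.errors import CoverageError

        with pytest.raises(CoverageError):
            correct_reflection_artifact(trace, t[: t.size // 2], d[: t.size // 2])


# ---------------------------------------------------------------------------
# Timebase alignment


class TestAlignTimebases:
    def _artifact_trace(self, shift_frames, n=100):
        t = np.arange(n) * FRAME
        d = np.zeros(n)
        d[40:52] = np.concatenate([np.linspace(0, 40, 6), np.linspace(40, 0, 6)])
        y = np.ones(n)
        idx = np.arange(n) - shift_frames
        inside = (idx >= 0) & (idx < n)
        y[inside] += 0.01 * d[idx[inside]]
        return FluorescenceTrace(t, y, state=NORMALIZED), t, d

    @pytest.mark.parametrize("shift", [0, 3, -2])
    def test_recovers_integer_frame_shift(self, shift):
        trace, t, d = self._artifact_trace(shift)
        lag = align_timebases(trace, t, d, max_lag=10 * FRAME)
        assert lag == pytest.approx(shift * FRAME, abs=1e-9)

    def test_shift_beyond_window_rejected(self):
        trace, t, d = self._artifact_trace(8)
        with pytest.raises(AlignmentUndefinedError):
            align_timebases(trace, t, d, max_lag=5 * FRAME)

    def test_flat_inputs_rejected(self):
        t = np.arange(100) * FRAME
        trace = FluorescenceTrace(t, np.ones(100), state=NORMALIZED)
        with pytest.raises(AlignmentUndefinedError):
            align_timebases(trace, t, np.zeros(100), max_lag=5 * FRAME)


# ---------------------------------------------------------------------------
# Noise estimation


class TestNoiseEstimation:
    def test_constant_trace_has_zero_noise(self):
        out = estimate_noise(make_trace(np.ones(40)))
        assert out.noise == 0.0

    def test_white_noise_recovered_within_15_percent(self, rng):
        y = 1 + rng.normal(0, 0.01, 500)
        out = estimate_noise(make_trace(y))
        assert out.noise == pytest.approx(0.01, rel=0.15)

    def test_selected_window_minimizes_absolute_slope(self, rng):
        # slow sinusoid + small noise: the flattest 20-frame stretch wins
        t = np.arange(120) * FRAME
        y = 1 + 0.2 * np.sin(2 * np.pi * t / 40.0) + rng.normal(0, 0.002, t.size)
        out = estimate_noise(make_trace(y))
        start = int(out.provenance[-1].split("start=")[1].split(",")[0])
        window = 20
        slopes = []
        for s in range(0, y.size - window + 1):
            w = y[s : s + window]
            slopes.append(abs(np.polyfit(np.arange(window), w, 1)[0]))
        assert abs(np.polyfit(np.arange(window), y[start : start + window], 1)[0]) == pytest.approx(
            min(slopes), rel=1e-9
        )

    def test_too_short_trace_rejected(self):
        from mechanoca.errors import NoiseUndefinedError

        with pytest.raises(NoiseUndefinedError):
            estimate_noise(make_trace(np.ones(10)))


# ---------------------------------------------------------------------------
# Detection threshold semantics


class TestDetection:
    def test_four_fold_threshold_is_strict(self):
        noise = 0.01
        base = gaussian_trace(amp=1.0)
        for mult, expected in [(3.9, 0), (4.0, 0), (4.1, 1)]:
            trace = make_trace(1 + (base.intensity - 1) * mult * noise, noise=noise)
            assert len(detect_transients(trace)) == expected

    def test_flat_trace_has_no_events(self):
        assert detect_transients(make_trace(np.ones(40), noise=0.01)) == []

    def test_two_separated_transients_in_order(self):
        t = np.arange(120) * FRAME
        y = (
            1
            + 1.0 * np.exp(-((t - 10) ** 2) / 2.0)
            + 0.5 * np.exp(-((t - 30) ** 2) / 2.0)
        )
        events = detect_transients(make_trace(y, noise=0.01))
        assert len(events) == 2
        assert events[0].peak < events[1].peak

    def test_detection_is_monotone_in_peak_height(self):
        noise = 0.01
        base = gaussian_trace(amp=1.0)
        detected = make_trace(1 + (base.intensity - 1) * 4.1 * noise, noise=noise)
        assert detect_transients(detected)
        for boost in (1.5, 3.0, 10.0):
            taller = make_trace(
                1 + (base.intensity - 1) * 4.1 * noise * boost, noise=noise
            )
            assert detect_transients(taller)

    def test_noise_precondition(self):
        with pytest.raises(PreconditionError):
            detect_transients(make_trace(np.ones(40)))


# ---------------------------------------------------------------------------
# Transient characterization


class TestCharacterization:
    def test_gaussian_fwhm_matches_closed_form(self):
        sigma = 0.5
        trace = gaussian_trace(amp=1.0, sigma=sigma, dt=0.05, n=450)
        trace.noise = 0.01
        (tr,) = quantify_transients(trace)
        expected = 2 * math.sqrt(2 * math.log(2)) * sigma  # 1.177 s
        assert tr.duration == pytest.approx(expected, abs=FRAME)
        assert tr.amplitude == pytest.approx(1.0, rel=0.01)
        assert tr.onset_time <= tr.peak_time

    def test_amount_is_amplitude_times_duration(self):
        trace = gaussian_trace(amp=0.8, sigma=1.2)
        trace.noise = 0.01
        for tr in quantify_transients(trace):
            assert tr.amount == tr.amplitude * tr.duration

    def test_asymmetric_triangle_fwhm(self):
        # rise over R, fall over D: width at half height = (R + D)/2
        dt = 0.05
        t = np.arange(400) * dt
        rise, fall = 1.0, 3.0
        peak_t = 8.0
        y = 1 + np.clip(
            np.minimum((t - (peak_t - rise)) / rise, (peak_t + fall - t) / fall), 0, 1
        )
        trace = make_trace(y, dt=dt, noise=0.01)
        (tr,) = quantify_transients(trace)
        assert tr.duration == pytest.approx((rise + fall) / 2, abs=FRAME)

    def test_truncated_transient_flagged_partial(self):
        t = np.arange(40) * FRAME
        y = 1 + np.exp(-((t - t[-1]) ** 2) / (2 * 4.0**2))  # rises into the end
        trace = make_trace(y, noise=0.01)
        (tr,) = quantify_transients(trace)
        assert tr.partial
        assert tr.duration is None and tr.amount is None

    def test_series_amplitudes_window_maxima(self):
        t = np.arange(60) * FRAME
        y = np.ones(60)
        y[10] = 1.5
        y[40] = 1.3
        trace = make_trace(y)
        amps = measure_series_amplitudes(trace, [t[5], t[30]])
        assert amps == [pytest.approx(0.5), pytest.approx(0.3)]


# ---------------------------------------------------------------------------
# Spontaneous-activity flag


class TestSpontaneousFlag:
    def _trace_with_pre_pulse(self, mult):
        noise = 0.01
        t = np.arange(100) * FRAME
        y = 1 + mult * noise * np.exp(-((t - 5.0) ** 2) / (2 * 0.8**2))
        return make_trace(y, noise=noise)

    def test_five_fold_pre_stimulus_pulse_flags(self):
        assert flag_spontaneous(self._trace_with_pre_pulse(5.0), (0.0, 10.0))

    def test_quiet_window_passes(self):
        trace = make_trace(np.ones(100), noise=0.01)
        assert not flag_spontaneous(trace, (0.0, 10.0))

    def test_exactly_four_fold_is_not_flagged(self):
        # shares the strict > 4x rule with detect_transients
        assert not flag_spontaneous(self._trace_with_pre_pulse(4.0), (0.0, 10.0))

    def test_window_outside_recording_rejected(self):
        trace = make_trace(np.ones(50), noise=0.01)
        with pytest.raises(GeometryError):
            flag_spontaneous(trace, (0.0, 100.0))
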