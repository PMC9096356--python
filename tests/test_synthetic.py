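"""Synthetic scene generators: determinism, ground-truth consistency, geometry."""

import numpy as np
import pytest

from vitalcam.geometry import distance_from_diagonal, corrected_diagonal
from vitalcam.synthetic import (
    SceneConfig,
    default_scene_calibration,
    generate_breathing_trace,
    generate_detection_fixture,
    generate_reflectance_traces,
    generate_thermal_sequence,
)
from vitalcam.thermal import ThermalCalibration


def dft_argmax_hz(x, fs):
    """Brute-force DFT argmax oracle (no windowing, positive bins)."""
    x = x - x.mean()
    n = x.size
    mags = [abs(np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))) for k in range(1, n // 2)]
    return (1 + int(np.argmax(mags))) * fs / n


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(fs=0.0),
            dict(duration_s=-1.0),
            dict(true_rr_bpm=3.0),
            dict(true_rr_bpm=1000.0),
            dict(true_hr_bpm=20.0),
            dict(distance_m=-2.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(**kwargs)

    def test_thermal_distance_range(self):
        with pytest.raises(ValueError, match="distance"):
            generate_thermal_sequence(SceneConfig(duration_s=1.0, distance_m=0.1))


class TestDeterminism:
    def test_breathing_trace_bit_identical_for_fixed_seed(self):
        cfg = SceneConfig(duration_s=5.0, seed=42)
        a, _ = generate_breathing_trace(cfg)
        b, _ = generate_breathing_trace(cfg)
        assert np.array_equal(a.values, b.values)

    def test_thermal_sequence_bit_identical_for_fixed_seed(self):
        cfg = SceneConfig(duration_s=2.0, seed=42)
        s1, d1, _ = generate_thermal_sequence(cfg)
        s2, d2, _ = generate_thermal_sequence(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert d1[0] == d2[0]

    def test_reflectance_traces_bit_identical_for_fixed_seed(self):
        cfg = SceneConfig(duration_s=5.0, seed=42)
        t1, _ = generate_reflectance_traces(cfg, a_s=0.02)
        t2, _ = generate_reflectance_traces(cfg, a_s=0.02)
        assert np.array_equal(t1.g, t2.g)

    def test_different_seeds_differ(self):
        a, _ = generate_breathing_trace(SceneConfig(duration_s=5.0, seed=1))
        b, _ = generate_breathing_trace(SceneConfig(duration_s=5.0, seed=2))
        assert not np.array_equal(a.values, b.values)


class TestBreathingTrace:
    def test_noiseless_trace_dominant_frequency_is_true_rate(self):
        cfg = SceneConfig(duration_s=30.0, true_rr_bpm=15.0, noise_sd=0.0, drift_amplitude=0.0)
        sig, gt = generate_breathing_trace(cfg, phase=0.0)
        assert dft_argmax_hz(sig.values, sig.fs) == pytest.approx(0.25, abs=1.0 / 30.0)
        assert gt.rr_bpm == 15.0

    @pytest.mark.parametrize("waveform", ["sinusoid", "fast_exhale"])
    def test_dominant_frequency_within_one_bin_for_any_waveform(self, waveform):
        cfg = SceneConfig(duration_s=20.0, true_rr_bpm=12.0, noise_sd=0.0, drift_amplitude=0.0)
        sig, _ = generate_breathing_trace(cfg, phase=0.3, waveform=waveform)
        assert dft_argmax_hz(sig.values, sig.fs) == pytest.approx(0.2, abs=1.0 / 20.0)

    def test_exhalation_peaks_are_maxima_at_pinned_phase(self):
        cfg = SceneConfig(duration_s=10.0, true_rr_bpm=6.0, noise_sd=0.0, drift_amplitude=0.0)
        sig, _ = generate_breathing_trace(cfg, phase=0.0)
        assert np.argmax(sig.values) == 0  # exhalation peak pinned to t = 0

    def test_trace_length(self):
        cfg = SceneConfig(duration_s=7.5, fs=30.0)
        sig, _ = generate_breathing_trace(cfg)
        assert sig.values.size == 225


class TestDetectionFixture:
    def test_one_metre_diagonal_value(self):
        det = generate_detection_fixture(1.0)
        assert corrected_diagonal(det) == pytest.approx(76.4129, abs=0.01)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("pose", [(0.0, 0.0), (15.0, -20.0)])
    def test_distance_round_trip_through_pose_correction(self, d, pose):
        det = generate_detection_fixture(d, pose)
        assert distance_from_diagonal(corrected_diagonal(det)) == pytest.approx(d, rel=1e-6)

    def test_closer_face_has_larger_diagonal(self):
        d2 = generate_detection_fixture(2.0).box.diagonal
        d5 = generate_detection_fixture(5.0).box.diagonal
        assert d2 > d5

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            generate_detection_fixture(0.0)


class TestThermalSequence:
    def test_zero_bias_forehead_reads_true_temperature(self):
        cfg = SceneConfig(duration_s=1.0, noise_sd=0.0, true_skin_temp_c=34.2)
        seq, dets, _ = generate_thermal_sequence(cfg, calib=ThermalCalibration.identity())
        from vitalcam.geometry import forehead_roi
        roi = forehead_roi(dets[0])
        assert seq.frames[0][roi.slices()].mean() == pytest.approx(34.2, abs=1e-5)

    def test_reading_decreases_with_distance_in_cold_room(self):
        from vitalcam.geometry import forehead_roi
        means = []
        for d in (2.0, 5.0):
            cfg = SceneConfig(duration_s=1.0, noise_sd=0.0, ambient_temp_c=19.0, distance_m=d)
            seq, dets, _ = generate_thermal_sequence(cfg)
            roi = forehead_roi(dets[0])
            means.append(seq.frames[0][roi.slices()].mean())
        assert means[1] < means[0]

    def test_mask_pixels_carry_breathing_trace(self):
        from vitalcam.geometry import mask_roi
        cfg = SceneConfig(duration_s=5.0, noise_sd=0.0, drift_amplitude=0.0, seed=8)
        seq, dets, gt = generate_thermal_sequence(cfg, calib=ThermalCalibration.identity())
        roi = mask_roi(dets[0])
        extracted = seq.frames[:, roi.slices()[0], roi.slices()[1]].mean(axis=(1, 2))
        assert np.allclose(extracted, gt.mask_trace_c, atol=1e-5)


class TestDefaultBias:
    def test_slope_is_negative_across_calibrated_ambients(self):
        calib = default_scene_calibration()
        for ta in (19.0, 23.0, 28.0):
            assert calib.slope(ta) < 0

    def test_cold_room_long_range_bias_magnitude(self):
        # worst case of the characterised conditions: ~-1.3 degC at 5 m, 19 degC
        calib = default_scene_calibration()
        assert calib.bias(19.0, 5.0) == pytest.approx(-1.3, abs=0.05)


class TestReflectanceTraces:
    def test_nonpositive_pulsatile_amplitude_rejected(self):
        with pytest.raises(ValueError):
            generate_reflectance_traces(SceneConfig(duration_s=5.0), a_p=0.0)

    def test_green_channel_carries_strongest_pulse(self):
        cfg = SceneConfig(duration_s=10.0, true_hr_bpm=66.0, seed=0)
        traces, _ = generate_reflectance_traces(cfg, a_p=0.02, a_s=0.0, noise_rel=0.0)
        rel_amp = [np.ptp(ch) / ch.mean() for ch in (traces.r, traces.g, traces.b)]
        assert rel_amp[1] == max(rel_amp)

    def test_ground_truth_mirrors_config(self):
        cfg = SceneConfig(duration_s=5.0, true_hr_bpm=88.0, distance_m=1.5, seed=6)
        _, gt = generate_reflectance_traces(cfg)
        assert gt.hr_bpm == 88.0 and gt.distance_m == 1.5 and gt.seed == 6
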