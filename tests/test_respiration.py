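"""Respiratory-rate estimation: window arithmetic, P2P, FFT, extraction."""

import numpy as np
import pytest

from vitalcam.geometry import BoundingBox, FaceDetection
from vitalcam.respiration import (
    BreathSignal,
    ThermalSequence,
    WindowSpec,
    extract_breath_signal,
    frequency_resolution_bpm,
    max_measurable_rr,
    min_window,
    respiratory_heat_loss,
    rr_fft,
    rr_p2p,
    screen_tachypnea,
)
from vitalcam.synthetic import SceneConfig, generate_breathing_trace, generate_thermal_sequence
from vitalcam.thermal import AmbientConditions


def sinusoid(rr_bpm, duration_s=30.0, fs=30.0, phase=0.0, noise_sd=0.0, seed=0):
    t = np.arange(int(round(duration_s * fs))) / fs
    x = 32.0 + 0.3 * np.cos(2 * np.pi * rr_bpm / 60.0 * t - phase)
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return BreathSignal(x, fs)


class TestWindowArithmetic:
    @pytest.mark.parametrize(
        "method, kwargs, expected_s",
        [
            ("FFT", dict(resolution_bpm=3.0), 20.0),
            ("FFT", dict(resolution_bpm=6.0), 10.0),
            ("P2P", dict(rr_min_bpm=6.0), 10.0),
        ],
    )
    def test_min_window(self, method, kwargs, expected_s):
        assert min_window(method, **kwargs) == pytest.approx(expected_s)

    def test_frequency_resolution_at_20s_is_3_bpm(self):
        assert frequency_resolution_bpm(20.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("fs, expected", [(30.0, 900.0), (2.0, 60.0), (1.0, 30.0)])
    def test_nyquist_bound_on_rr(self, fs, expected):
        assert max_measurable_rr(fs) == pytest.approx(expected)

    def test_window_below_method_minimum_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(5.0, "P2P")
        with pytest.raises(ValueError):
            WindowSpec(15.0, "FFT")


class TestP2P:
    def test_noiseless_sinusoid_period_4s(self):
        est = rr_p2p(sinusoid(15.0, duration_s=10.0), 10.0)
        assert est.rr_bpm == pytest.approx(15.0, abs=0.3)

    def test_slowest_breath_one_period_in_minimum_window(self):
        # 6 BPM has a 10 s period: exactly one full cycle in the 10 s window,
        # with exhalation peaks at both window edges
        cfg = SceneConfig(duration_s=10, true_rr_bpm=6, noise_sd=0.0, drift_amplitude=0.0)
        sig, _ = generate_breathing_trace(cfg, phase=0.0)
        est = rr_p2p(sig, 10.0)
        assert est.rr_bpm == pytest.approx(6.0, abs=0.3)

    def test_flat_signal_is_indeterminate_not_a_number(self):
        est = rr_p2p(BreathSignal(np.full(600, 31.0), 30.0), 10.0)
        assert est.rr_bpm is None and est.reason is not None

    def test_window_shorter_than_minimum_rejected(self):
        with pytest.raises(ValueError):
            rr_p2p(sinusoid(15.0), 5.0)

    @pytest.mark.parametrize("rr", [6.0, 12.0, 20.0, 35.0])
    def test_recovers_rate_across_range_with_noise_and_drift(self, rr):
        errs = []
        for seed in range(10):
            cfg = SceneConfig(
                duration_s=10, true_rr_bpm=rr, noise_sd=0.03, drift_amplitude=0.1, seed=seed
            )
            sig, _ = generate_breathing_trace(cfg)
            est = rr_p2p(sig, 10.0)
            assert est.determinate
            errs.append(abs(est.rr_bpm - rr))
        assert np.mean(errs) <= 2.0


class TestFFT:
    def test_off_bin_sinusoid_reported_at_nearest_bin(self):
        # 0.25 Hz falls between the 14 and 16 BPM bins of a 30 s window
        est = rr_fft(sinusoid(15.0, duration_s=30.0), 30.0)
        assert est.rr_bpm == pytest.approx(15.0, abs=1.0)

    def test_on_bin_sinusoid_exact(self):
        est = rr_fft(sinusoid(16.0, duration_s=30.0), 30.0)  # 16 BPM on-bin at 2 BPM bins
        assert est.rr_bpm == pytest.approx(16.0, abs=1e-9)

    def test_white_noise_flagged_or_indeterminate(self):
        x = np.random.default_rng(7).normal(0, 1, 900)
        est = rr_fft(BreathSignal(x, 30.0), 30.0)
        assert (not est.determinate) or est.low_confidence

    def test_flat_signal_indeterminate(self):
        est = rr_fft(BreathSignal(np.full(900, 30.0), 30.0), 30.0)
        assert est.rr_bpm is None

    def test_window_below_20s_rejected(self):
        with pytest.raises(ValueError):
            rr_fft(sinusoid(15.0), 15.0)

    def test_matches_brute_force_dft_argmax_oracle(self):
        """The estimator must agree with an independent DFT-argmax oracle."""
        for seed in range(10):
            rr = float(np.random.default_rng(seed).uniform(7, 34))
            cfg = SceneConfig(
                duration_s=30, true_rr_bpm=rr, noise_sd=0.03, drift_amplitude=0.1, seed=seed
            )
            sig, _ = generate_breathing_trace(cfg)
            est = rr_fft(sig, 30.0)
            # oracle: naive DFT magnitudes over the in-band bins of the
            # mean-removed raw trace, implemented without np.fft
            x = sig.values - sig.values.mean()
            n = x.size
            t = np.arange(n)
            best, best_mag = None, -1.0
            for k in range(1, n // 2 + 1):
                f = k * sig.fs / n
                if not (0.08 <= f <= 0.7):
                    continue
                mag = abs(np.sum(x * np.exp(-2j * np.pi * k * t / n)))
                if mag > best_mag:
                    best, best_mag = f, mag
            assert est.rr_bpm == pytest.approx(60.0 * best, abs=1e-9)

    def test_tachypnea_flag_set_from_estimate(self):
        est = rr_fft(sinusoid(24.0, duration_s=30.0), 30.0)
        assert est.tachypnea_flag is True


class TestTachypneaScreen:
    @pytest.mark.parametrize("rr, expected", [(21.0, True), (20.0, False), (6.0, False)])
    def test_strict_threshold_at_20(self, rr, expected):
        assert screen_tachypnea(rr) is expected


class TestHeatLoss:
    def test_vanishes_at_exhaled_air_conditions(self):
        assert respiratory_heat_loss(100.0, AmbientConditions(34.0, 5.87)) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # 0.0014*100*(34-24) + 0.0173*100*(5.87-3.87) = 1.4 + 3.46
        val = respiratory_heat_loss(100.0, AmbientConditions(24.0, 3.87))
        assert val == pytest.approx(4.86, abs=1e-9)

    def test_linear_in_metabolic_rate(self):
        amb = AmbientConditions(20.0, 4.0)
        assert respiratory_heat_loss(200.0, amb) == pytest.approx(
            2 * respiratory_heat_loss(100.0, amb)
        )


class TestExtraction:
    def _scene(self, **kw):
        cfg = SceneConfig(duration_s=12.0, noise_sd=kw.pop("noise_sd", 0.0),
                          drift_amplitude=0.0, seed=3, **kw)
        return generate_thermal_sequence(cfg)

    def test_extracted_signal_tracks_injected_modulation(self):
        seq, dets, gt = self._scene()
        sig = extract_breath_signal(seq, dets)
        assert sig.normalized
        r = np.corrcoef(sig.values, gt.mask_trace_c)[0, 1]
        assert r > 0.99

    def test_constant_sequence_returned_raw_with_flag(self):
        frames = np.full((60, 30, 30), 30.0, dtype=np.float32)
        det = FaceDetection(BoundingBox(2, 2, 20, 24), y_eye=12)
        sig = extract_breath_signal(ThermalSequence(frames, 30.0), [det] * 60)
        assert not sig.normalized
        assert np.allclose(sig.values, 30.0)

    def test_short_detection_gaps_are_bridged(self):
        seq, dets, _ = self._scene()
        dets = list(dets)
        dets[100:103] = [None, None, None]
        sig = extract_breath_signal(seq, dets)
        assert sig.values.size == seq.n_frames

    def test_long_gap_errors(self):
        seq, dets, _ = self._scene()
        dets = list(dets)
        dets[100:107] = [None] * 7
        with pytest.raises(ValueError, match="gap"):
            extract_breath_signal(seq, dets)
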