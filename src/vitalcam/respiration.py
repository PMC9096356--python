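"""Respiratory-rate estimation from facemask thermography.

A facemask traps a small "microenvironment" of exhaled air, so the mean
temperature of the mask region of a thermal video oscillates at the breathing
frequency: exhalation produces peaks, inhalation troughs. The per-frame mean
of the mask-ROI pixels is the raw breathing signal; respiratory rate (RR) is
then estimated either

* in the time domain (**P2P**): detect extrema of the detrended signal and
  convert the mean interval between successive peaks into breaths/min, or
* in the frequency domain (**FFT**): detrend, low-pass filter, and take the
  frequency of the largest magnitude in the physiological band.

Window-size constraints follow from first principles: the FFT bin width is
the reciprocal of the window length (so a 3 BPM resolution needs 20 s), the
P2P method needs one full period of the slowest breath between two peaks
(10 s for 6 BPM), and the Nyquist bound caps measurable RR at 30·fs BPM.
Tachypnea is flagged strictly above 20 breaths/min.

Also provided is the standard respiratory heat-exchange estimate (convective
plus evaporative losses as a function of metabolic rate, ambient temperature
and ambient pressure) that motivates the facemask thermal signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .geometry import FaceDetection, mask_roi
from .thermal import AmbientConditions

__all__ = [
    "BreathSignal",
    "WindowSpec",
    "RREstimate",
    "ThermalSequence",
    "extract_breath_signal",
    "rr_p2p",
    "rr_fft",
    "min_window",
    "max_measurable_rr",
    "frequency_resolution_bpm",
    "screen_tachypnea",
    "respiratory_heat_loss",
    "TACHYPNEA_THRESHOLD_BPM",
    "RR_BAND_HZ",
]

TACHYPNEA_THRESHOLD_BPM = 20.0

#: Physiological search band for the spectral RR estimator (Hz), ~5-42 BPM.
RR_BAND_HZ = (0.08, 0.7)

#: Zero-phase low-pass applied before the FFT estimator.
_LOWPASS_CUTOFF_HZ = 1.0
_LOWPASS_ORDER = 4

#: Peak detection: minimum prominence as a fraction of the signal IQR, and
#: minimum spacing from the upper edge of the search band.
_PROMINENCE_IQR_FRACTION = 0.2

#: Spectral peak-to-median magnitude ratio below which an FFT estimate is
#: flagged low-confidence (no clear periodic component).
_LOW_CONFIDENCE_RATIO = 5.0

#: Maximum number of consecutive missing detections bridged by carrying the
#: previous mask ROI forward.
_MAX_GAP_FRAMES = 5


@dataclass(frozen=True)
class ThermalSequence:
    """Time-ordered stack of 2-D temperature grids (°C) at fixed frame rate."""

    frames: np.ndarray  # (n_frames, height, width)
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")
        if np.asarray(self.frames).ndim != 3:
            raise ValueError("frames must be a (time, row, col) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs


@dataclass(frozen=True)
class BreathSignal:
    """Mask-ROI mean-temperature trace.

    ``normalized`` marks whether values were min-max scaled to [0, 1]; a
    constant input trace cannot be normalized and is returned raw with the
    flag unset.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("breathing signal must be 1-D with at least 2 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.normalized and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("normalized signal must lie within [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window for one RR estimate."""

    t_w_s: float
    method: Literal["P2P", "FFT"]

    def __post_init__(self) -> None:
        if self.method not in ("P2P", "FFT"):
            raise ValueError("method must be 'P2P' or 'FFT'")
        floor = min_window(self.method)
        if self.t_w_s < floor - 1e-9:
            raise ValueError(
                f"window {self.t_w_s} s below the {floor} s minimum for {self.method}"
            )


@dataclass(frozen=True)
class RREstimate:
    """One respiratory-rate estimate; ``rr_bpm`` is None when indeterminate."""

    rr_bpm: float | None
    method: str
    window_s: float
    tachypnea_flag: bool | None = None
    low_confidence: bool = False
    reason: str | None = None

    @property
    def determinate(self) -> bool:
        return self.rr_bpm is not None


# ---------------------------------------------------------------------------
# Signal extraction
# ---------------------------------------------------------------------------

def extract_breath_signal(
    seq: ThermalSequence,
    dets: Sequence[FaceDetection | None],
    normalize: bool = True,
) -> BreathSignal:
    """Mask-ROI mean temperature per frame, optionally min-max normalized.

    Frames with a missing detection reuse the previous frame's mask ROI for
    up to 5 consecutive frames; longer gaps raise.
    """
    if len(dets) != seq.n_frames:
        raise ValueError(f"{len(dets)} detections for {seq.n_frames} frames")
    values = np.empty(seq.n_frames)
    roi = None
    gap = 0
    for i, det in enumerate(dets):
        if det is not None:
            roi = mask_roi(det)
            gap = 0
        else:
            gap += 1
            if roi is None or gap > _MAX_GAP_FRAMES:
                raise ValueError(f"detection gap of {gap} frames at frame {i} exceeds limit")
        values[i] = seq.frames[i][roi.slices()].mean()
    if normalize:
        lo, hi = values.min(), values.max()
        if hi - lo > 1e-9:
            return BreathSignal((values - lo) / (hi - lo), seq.fs, normalized=True)
    return BreathSignal(values, seq.fs, normalized=False)


def _window_slice(sig: BreathSignal, t_w_s: float) -> np.ndarray:
    n = int(round(t_w_s * sig.fs))
    if n > sig.values.size:
        raise ValueError(
            f"window of {t_w_s} s needs {n} samples; signal has {sig.values.size}"
        )
    return sig.values[:n]


def _detrend(x: np.ndarray, fs: float, ma_window_s: float = 10.0) -> np.ndarray:
    """Remove slow drift by subtracting a centred moving average."""
    n = min(x.size, max(3, int(round(ma_window_s * fs))))
    if n % 2 == 0:
        n -= 1  # centred kernel must be odd
    kernel = np.ones(n) / n
    core = np.convolve(x, kernel, mode="valid")
    # constant-extend the trend at the edges: signal-padding there would
    # track the edges themselves and suppress edge extrema
    pad = n // 2
    trend = np.concatenate([np.full(pad, core[0]), core, np.full(pad, core[-1])])
    return x - trend


# ---------------------------------------------------------------------------
# Time-domain (peak-to-peak) estimator
# ---------------------------------------------------------------------------

def _extrema(
    x: np.ndarray, fs: float, rr_max_bpm: float,
    prom_frac: float = _PROMINENCE_IQR_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Interior peaks/troughs plus qualifying window-edge extrema.

    Edge samples are not seen by standard peak finding, yet at the minimum
    window (one breath period per window) the true extrema frequently sit at
    the window edges. An edge sample is accepted as a peak (trough) when the
    signal leaves it in the falling (rising) direction, its height is within
    90 % of the global extremum, and it respects the minimum spacing.
    """
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    prominence = prom_frac * iqr if iqr > 0 else None
    distance = max(1, int(round(60.0 / rr_max_bpm * fs)))

    def one_sign(y: np.ndarray) -> np.ndarray:
        idx, _ = sps.find_peaks(y, prominence=prominence, distance=distance)
        idx = list(idx)
        span = y.max() - y.min()
        if span > 0:
            thresh = y.max() - 0.1 * span
            if y[0] > y[1] and y[0] >= thresh and (not idx or idx[0] >= distance):
                idx.insert(0, 0)
            last = y.size - 1
            if y[last] > y[last - 1] and y[last] >= thresh and (
                not idx or last - idx[-1] >= distance
            ):
                idx.append(last)
        return np.asarray(idx, dtype=int)

    return one_sign(x), one_sign(-x)


def rr_p2p(
    sig: BreathSignal,
    window: WindowSpec | float = 10.0,
    rr_max_bpm: float = RR_BAND_HZ[1] * 60.0,
) -> RREstimate:
    """Time-domain RR: 60 / mean inter-peak interval of the smoothed,
    detrended signal (the same zero-phase low-pass as the spectral method;
    unsmoothed, sensor-noise wiggles between slow breaths masquerade as
    extrema).

    Trough-trough intervals are pooled with peak-peak intervals (both measure
    the breath period). When the window holds only a single peak and a single
    trough — the minimum-window regime for the slowest breaths — the
    peak-trough spacing is doubled as a half-period fallback.
    """
    if isinstance(window, WindowSpec):
        if window.method != "P2P":
            raise ValueError("window spec is not for the P2P method")
        t_w = window.t_w_s
    else:
        t_w = float(window)
        WindowSpec(t_w, "P2P")  # validates the minimum window
    raw = _window_slice(sig, t_w)
    if np.ptp(raw) <= 1e-9 * max(1.0, abs(float(np.mean(raw)))):
        return RREstimate(None, "P2P", t_w, reason="flat_signal")
    x = _detrend(_lowpass(raw, sig.fs), sig.fs)
    peaks, troughs = _extrema(x, sig.fs, rr_max_bpm)
    if peaks.size + troughs.size < 2:
        # one breath period per window: prominence of near-edge extrema is
        # clipped at the window edge, so retry with a relaxed threshold
        peaks, troughs = _extrema(x, sig.fs, rr_max_bpm,
                                  prom_frac=_PROMINENCE_IQR_FRACTION / 2)

    intervals = []
    for idx in (peaks, troughs):
        if idx.size >= 2:
            intervals.extend(np.diff(idx) / sig.fs)
    min_gap = max(1, int(round(60.0 / rr_max_bpm * sig.fs)))
    if intervals:
        period_s = float(np.mean(intervals))
    elif peaks.size == 1 and troughs.size == 1:
        period_s = 2.0 * abs(int(peaks[0]) - int(troughs[0])) / sig.fs
    elif (
        np.ptp(x) > 1e-9
        and abs(int(np.argmax(x)) - int(np.argmin(x))) >= min_gap
    ):
        # last resort for a single breath spanning the window with one
        # extremum hard against the edge: global max/min are that breath's
        # exhalation peak and inhalation trough half a period apart
        period_s = 2.0 * abs(int(np.argmax(x)) - int(np.argmin(x))) / sig.fs
    else:
        return RREstimate(None, "P2P", t_w, reason="fewer_than_two_extrema")
    if period_s <= 0:
        return RREstimate(None, "P2P", t_w, reason="degenerate_period")
    rr = 60.0 / period_s
    return RREstimate(rr, "P2P", t_w, tachypnea_flag=screen_tachypnea(rr))


# ---------------------------------------------------------------------------
# Frequency-domain (FFT) estimator
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if _LOWPASS_CUTOFF_HZ >= nyq:
        return x
    sos = sps.butter(_LOWPASS_ORDER, _LOWPASS_CUTOFF_HZ / nyq, btype="low", output="sos")
    return sps.sosfiltfilt(sos, x)


def rr_fft(
    sig: BreathSignal,
    window: WindowSpec | float = 30.0,
    band_hz: tuple[float, float] = RR_BAND_HZ,
    zero_pad: int = 1,
) -> RREstimate:
    """Spectral RR: frequency of the largest magnitude in the breathing band.

    The signal is detrended, low-pass filtered and transformed; the bin width
    is 1/t_w Hz (``zero_pad`` > 1 interpolates the spectrum on a finer grid
    but adds no true resolution). A peak less than 5x the median in-band
    magnitude is flagged low-confidence.
    """
    if isinstance(window, WindowSpec):
        if window.method != "FFT":
            raise ValueError("window spec is not for the FFT method")
        t_w = window.t_w_s
    else:
        t_w = float(window)
        WindowSpec(t_w, "FFT")
    x = _window_slice(sig, t_w)
    if np.ptp(x) <= 1e-9 * max(1.0, abs(float(np.mean(x)))):
        return RREstimate(None, "FFT", t_w, reason="flat_signal")
    x = sps.detrend(x)
    x = _lowpass(x, sig.fs)

    n = x.size
    nfft = n * max(1, int(zero_pad))
    mag = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sig.fs)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(in_band):
        return RREstimate(None, "FFT", t_w, reason="empty_band")
    band_mag = mag[in_band]
    if not np.any(band_mag > 0):
        return RREstimate(None, "FFT", t_w, reason="zero_spectrum")
    k = int(np.argmax(band_mag))
    rr = 60.0 * float(freqs[in_band][k])
    med = float(np.median(band_mag))
    low_conf = med > 0 and float(band_mag[k]) / med < _LOW_CONFIDENCE_RATIO
    return RREstimate(
        rr, "FFT", t_w,
        tachypnea_flag=screen_tachypnea(rr),
        low_confidence=low_conf,
    )


# ---------------------------------------------------------------------------
# Window-size and sampling arithmetic
# ---------------------------------------------------------------------------

def min_window(
    method: Literal["P2P", "FFT"],
    rr_min_bpm: float = 6.0,
    resolution_bpm: float = 3.0,
) -> float:
    """Minimum analysis window (s) for a method.

    FFT: the bin width 1/t_w must not exceed the requested resolution, so
    t_w = 60/resolution_bpm. P2P: one full period of the slowest breath must
    separate two peaks, so t_w = 60/rr_min_bpm.
    """
    if method == "FFT":
        if resolution_bpm <= 0:
            raise ValueError("resolution must be positive")
        return 60.0 / resolution_bpm
    if method == "P2P":
        if rr_min_bpm <= 0:
            raise ValueError("minimum RR must be positive")
        return 60.0 / rr_min_bpm
    raise ValueError(f"unknown method {method!r}")


def frequency_resolution_bpm(t_w_s: float) -> float:
    """FFT bin width in BPM for a window of t_w seconds (60/t_w)."""
    if t_w_s <= 0:
        raise ValueError("window must be positive")
    return 60.0 / t_w_s


def max_measurable_rr(fs: float) -> float:
    """Nyquist bound on measurable RR (BPM): 60 * fs / 2."""
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    return 60.0 * fs / 2.0


def screen_tachypnea(rr_bpm: float, threshold_bpm: float = TACHYPNEA_THRESHOLD_BPM) -> bool:
    """Tachypnea screen: RR strictly greater than the threshold (default 20 BPM)."""
    return rr_bpm > threshold_bpm


# ---------------------------------------------------------------------------
# Respiratory heat exchange
# ---------------------------------------------------------------------------

def respiratory_heat_loss(m_w_m2: float, ambient: AmbientConditions) -> float:
    """Convective + evaporative respiratory heat loss (W/m²).

    C_res + E_res = 0.0014·M·(34 − T_ambient) + 0.0173·M·(5.87 − P_a),
    with M the metabolic rate (W/m²), T_ambient in °C and P_a in kPa.
    Both terms vanish for exhaled-air-like ambient conditions (34 °C,
    5.87 kPa vapour pressure); the loss scales linearly with M.
    """
    if m_w_m2 <= 0:
        raise ValueError("metabolic rate must be positive")
    return 0.0014 * m_w_m2 * (34.0 - ambient.t_ambient_c) + 0.0173 * m_w_m2 * (
        5.87 - ambient.p_a_kpa
    )
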