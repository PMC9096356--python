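"""Heart-rate estimation from tri-channel facial reflectance (POS method).

Remote photoplethysmography treats the light reflected by skin as a
dichromatic mixture: a specular component (surface reflection, carrying no
physiology, common to all colour channels after normalization) and a small
pulsatile component driven by blood-volume changes, strongest in green. The
plane-orthogonal-to-skin (POS) algorithm:

1. **Temporal normalization** — divide each channel by its temporal mean over
   the analysis window, so intensity (illumination level, shutter, gain)
   cancels exactly.
2. **Projection** — map the three normalized channels onto two axes through
   the projection matrix ``P = [[0, 1, -1], [-2, 1, 1]]``. Both rows sum to
   zero, so any common-mode (specular) signal is annihilated.
3. **Alpha tuning** — combine the two projections as
   ``h = S1 + (sigma(S1)/sigma(S2)) * S2``; in-phase projections add
   constructively while antiphase ones cancel, suppressing residual
   distortions.

The pulse signal is assembled with the standard sliding-window overlap-add
(window 1.6 s), band-pass filtered to the cardiac band (0.7-4 Hz) and the
heart rate taken as the frequency of the spectral peak. Tachycardia is
flagged strictly above 100 BPM. Channel order is fixed as (r, g, b) =
(630, 532, 465 nm); traces carry labels that are validated so a silent
channel swap cannot corrupt the projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ChannelTraces",
    "PulseSignal",
    "HREstimate",
    "POS_PROJECTION",
    "temporal_normalize",
    "pos_project",
    "pos_combine",
    "pos_pulse",
    "estimate_hr",
    "estimate_hr_from_traces",
    "screen_tachycardia",
    "HR_BAND_HZ",
    "TACHYCARDIA_THRESHOLD_BPM",
    "DEFAULT_LATENCY_S",
    "POS_WINDOW_S",
]

#: POS projection matrix; each row sums to zero (kills common-mode signals).
POS_PROJECTION = np.array([[0.0, 1.0, -1.0], [-2.0, 1.0, 1.0]])

#: Cardiac spectral band (Hz), 42-240 BPM.
HR_BAND_HZ = (0.7, 4.0)

TACHYCARDIA_THRESHOLD_BPM = 100.0

#: Seconds of signal recorded before the first HR estimate.
DEFAULT_LATENCY_S = 10.0

#: Sliding-window length for the POS overlap-add (the rPPG convention).
POS_WINDOW_S = 1.6

#: Zero-padding factor for the HR spectrum (finer peak localisation).
_HR_NFFT_PAD = 4

_EXPECTED_CHANNELS = ("r", "g", "b")


@dataclass(frozen=True)
class ChannelTraces:
    """Time-aligned mean-intensity traces of the forehead ROI.

    Channel order is (r, g, b) = (630, 532, 465 nm); ``channels`` labels are
    validated against this convention. Means must be strictly positive for
    temporal normalization to be defined.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float
    channels: tuple[str, str, str] = _EXPECTED_CHANNELS

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.g, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "b", b)
        if not (r.shape == g.shape == b.shape) or r.ndim != 1 or r.size < 2:
            raise ValueError("channels must be equal-length 1-D traces with >= 2 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if tuple(self.channels) != _EXPECTED_CHANNELS:
            raise ValueError(
                f"channel order must be {_EXPECTED_CHANNELS}, got {tuple(self.channels)}"
            )

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def stack(self) -> np.ndarray:
        """(3, n) array in (r, g, b) order."""
        return np.vstack([self.r, self.g, self.b])


@dataclass(frozen=True)
class PulseSignal:
    """POS pulse trace with the intermediate projected signals."""

    h: np.ndarray
    fs: float
    s1: np.ndarray | None = None
    s2: np.ndarray | None = None


@dataclass(frozen=True)
class HREstimate:
    """One heart-rate estimate; ``hr_bpm`` is None when indeterminate."""

    hr_bpm: float | None
    latency_s: float
    tachycardia_flag: bool | None = None
    reason: str | None = None

    @property
    def determinate(self) -> bool:
        return self.hr_bpm is not None


# ---------------------------------------------------------------------------
# POS building blocks
# ---------------------------------------------------------------------------

def temporal_normalize(traces: np.ndarray) -> np.ndarray:
    """Divide each channel by its temporal mean, making each mean exactly 1.

    ``traces`` is a (3, n) array. Scaling all channels by any positive
    constant leaves the output unchanged — the step that makes POS invariant
    to illumination intensity.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] != 3:
        raise ValueError("expected a (3, n) channel array")
    means = traces.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ValueError("non-positive channel mean: saturated or invalid ROI")
    return traces / means


def pos_project(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project normalized (3, n) channels to (S1, S2) = (g - b, -2r + g + b)."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.ndim != 2 or normalized.shape[0] != 3:
        raise ValueError("expected a (3, n) normalized channel array")
    s = POS_PROJECTION @ normalized
    return s[0], s[1]


def pos_combine(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Alpha-tuned combination h = S1 + (sigma(S1)/sigma(S2)) * S2.

    If S2 carries no variance the ratio is undefined; h falls back to S1
    (with a warning) rather than failing.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.size < 2:
        raise ValueError("S1 and S2 must be equal-length with >= 2 samples")
    sd2 = s2.std()
    if sd2 == 0:
        warnings.warn("sigma(S2) = 0; falling back to h = S1", stacklevel=2)
        return s1.copy()
    return s1 + (s1.std() / sd2) * s2


def pos_pulse(
    traces: ChannelTraces,
    window_s: float = POS_WINDOW_S,
    sliding: bool = True,
) -> PulseSignal:
    """Full POS pulse extraction.

    With ``sliding=True`` (default) the normalize/project/combine steps run
    per sliding window with mean-centred overlap-add, the convention of the
    rPPG literature; otherwise a single pass over the whole record.
    """
    c = traces.stack()
    n = traces.n
    win = max(2, int(round(window_s * traces.fs)))
    if not sliding or win >= n:
        cn = temporal_normalize(c)
        s1, s2 = pos_project(cn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = pos_combine(s1, s2)
        return PulseSignal(h - h.mean(), traces.fs, s1, s2)

    h = np.zeros(n)
    for end in range(win, n + 1):
        sl = slice(end - win, end)
        cn = temporal_normalize(c[:, sl])
        s1, s2 = pos_project(cn)
        sd2 = s2.std()
        hw = s1 if sd2 == 0 else s1 + (s1.std() / sd2) * s2
        h[sl] += hw - hw.mean()
    return PulseSignal(h, traces.fs)


# ---------------------------------------------------------------------------
# Spectral HR estimation
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.99 * nyq)
    if hi <= band[0]:
        return x
    sos = sps.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def estimate_hr(
    pulse: PulseSignal,
    latency_s: float = DEFAULT_LATENCY_S,
    band_hz: tuple[float, float] = HR_BAND_HZ,
) -> HREstimate:
    """Heart rate from the spectral peak of the first ``latency_s`` seconds.

    The pulse is band-pass filtered to the cardiac band and a Hann-windowed
    periodogram (zero-padded 4x for finer peak localisation) is searched for
    its in-band maximum; HR = 60 times the peak frequency.
    """
    n = int(round(latency_s * pulse.fs))
    if n < 2:
        raise ValueError("latency too short for the sampling rate")
    if pulse.h.size < n:
        raise ValueError(
            f"pulse signal of {pulse.h.size / pulse.fs:.1f} s shorter than "
            f"latency {latency_s} s"
        )
    x = pulse.h[:n]
    if np.allclose(x, x[0]):
        return HREstimate(None, latency_s, reason="no_pulsatile_content")
    x = _bandpass(x - x.mean(), pulse.fs, band_hz)

    nfft = n * _HR_NFFT_PAD
    freqs, psd = sps.periodogram(x, fs=pulse.fs, window="hann", nfft=nfft)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(in_band) or not np.any(psd[in_band] > 0):
        return HREstimate(None, latency_s, reason="zero_spectrum")
    hr = 60.0 * float(freqs[in_band][np.argmax(psd[in_band])])
    return HREstimate(hr, latency_s, tachycardia_flag=screen_tachycardia(hr))


def screen_tachycardia(
    hr_bpm: float, threshold_bpm: float = TACHYCARDIA_THRESHOLD_BPM
) -> bool:
    """Tachycardia screen: HR strictly greater than the threshold (default 100 BPM)."""
    return hr_bpm > threshold_bpm


def estimate_hr_from_traces(
    traces: ChannelTraces, latency_s: float = DEFAULT_LATENCY_S
) -> HREstimate:
    """Convenience: POS pulse extraction followed by spectral HR estimation."""
    return estimate_hr(pos_pulse(traces), latency_s=latency_s)
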