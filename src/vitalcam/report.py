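"""Screening pipeline: tie temperature, respiration and pulse into one report.

Two operating modes mirror the intended clinical use:

* **quick** — everything from the first 10 s of input: skin temperature
  compensated for ambient/distance, respiratory rate by the time-domain P2P
  method over a 10 s window, heart rate at 10 s latency;
* **monitor** — continuous monitoring: one FFT respiratory-rate estimate per
  sliding 30 s window (plus the quick-screen vitals for the report header).

A stage that cannot produce a number (missing input, indeterminate
estimate) propagates an explicit null with a reason code — never a
fabricated value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import FaceDetection, forehead_roi, estimate_distance
from .pulse import ChannelTraces, estimate_hr_from_traces
from .respiration import (
    BreathSignal,
    RREstimate,
    ThermalSequence,
    extract_breath_signal,
    rr_fft,
    rr_p2p,
)
from .thermal import (
    AmbientConditions,
    ThermalCalibration,
    compensate_temperature,
    mean_roi_temperature,
    screen_fever,
    DEFAULT_FEVER_MARGIN_C,
)

logger = logging.getLogger("vitalcam")

__all__ = ["ScreeningConfig", "VitalsReport", "run_screening", "write_report", "read_report"]

_REPORT_SCHEMA = "vitalcam.report.v1"


@dataclass(frozen=True)
class ScreeningConfig:
    """Pipeline configuration; defaults are the quick-screen settings."""

    mode: Literal["quick", "monitor"] = "quick"
    fever_baseline_c: float = 34.0
    fever_margin_c: float = DEFAULT_FEVER_MARGIN_C
    quick_window_s: float = 10.0
    monitor_window_s: float = 30.0
    monitor_step_s: float = 30.0
    hr_latency_s: float = 10.0
    roi_stat: Literal["mean", "max", "p95"] = "mean"


@dataclass(frozen=True)
class VitalsReport:
    """Machine-readable screening outcome; missing vitals are None + reason."""

    subject_id: str
    timestamp: str
    mode: str
    t_ir_c: float | None = None
    t_compensated_c: float | None = None
    fever_flag: bool | None = None
    rr_bpm: float | None = None
    rr_method: str | None = None
    rr_window_s: float | None = None
    tachypnea_flag: bool | None = None
    hr_bpm: float | None = None
    hr_latency_s: float | None = None
    tachycardia_flag: bool | None = None
    d_m: float | None = None
    t_ambient_c: float | None = None
    rr_series: tuple = ()
    reasons: tuple = ()

    def to_dict(self) -> dict:
        return {
            "schema": _REPORT_SCHEMA,
            "subject_id": self.subject_id,
            "timestamp": self.timestamp,
            "mode": self.mode,
            "t_ir_c": self.t_ir_c,
            "t_compensated_c": self.t_compensated_c,
            "fever_flag": self.fever_flag,
            "rr_bpm": self.rr_bpm,
            "rr_method": self.rr_method,
            "rr_window_s": self.rr_window_s,
            "tachypnea_flag": self.tachypnea_flag,
            "hr_bpm": self.hr_bpm,
            "hr_latency_s": self.hr_latency_s,
            "tachycardia_flag": self.tachycardia_flag,
            "d_m": self.d_m,
            "t_ambient_c": self.t_ambient_c,
            "rr_series": [list(x) for x in self.rr_series],
            "reasons": list(self.reasons),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "VitalsReport":
        if payload.get("schema") != _REPORT_SCHEMA:
            raise ValueError(f"unrecognised report schema: {payload.get('schema')!r}")
        kwargs = {k: v for k, v in payload.items() if k != "schema"}
        kwargs["rr_series"] = tuple(tuple(x) for x in kwargs.get("rr_series", []))
        kwargs["reasons"] = tuple(kwargs.get("reasons", []))
        return cls(**kwargs)


def _quick_rr(sig: BreathSignal, cfg: ScreeningConfig) -> RREstimate:
    return rr_p2p(sig, cfg.quick_window_s)


def _monitor_rr_series(sig: BreathSignal, cfg: ScreeningConfig) -> list[tuple[float, float | None]]:
    """(window start s, RR or None) per sliding FFT window."""
    out = []
    n_win = int(round(cfg.monitor_window_s * sig.fs))
    step = max(1, int(round(cfg.monitor_step_s * sig.fs)))
    for start in range(0, sig.values.size - n_win + 1, step):
        chunk = BreathSignal(sig.values[start : start + n_win], sig.fs, normalized=False)
        est = rr_fft(chunk, cfg.monitor_window_s)
        out.append((start / sig.fs, est.rr_bpm))
    return out


def run_screening(
    thermal: ThermalSequence | None,
    detections: Sequence[FaceDetection | None] | None,
    traces: ChannelTraces | None,
    ambient: AmbientConditions,
    calibration: ThermalCalibration,
    config: ScreeningConfig = ScreeningConfig(),
    subject_id: str = "anonymous",
) -> VitalsReport:
    """Run the full screening pipeline on whatever inputs are available."""
    reasons: list[str] = []
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    t_ir = t_comp = fever = rr = tachypnea = hr = tachy = d_m = None
    rr_method = rr_window = hr_latency = None
    rr_series: list[tuple[float, float | None]] = []

    if thermal is None or detections is None:
        reasons.append("no_thermal_input")
        logger.info("stage=thermal status=skipped reason=no_thermal_input")
    else:
        first_det = next((d for d in detections if d is not None), None)
        if first_det is None:
            reasons.append("no_face_detected")
        else:
            d_m = estimate_distance(first_det).d_m
            n_quick = min(thermal.n_frames, int(round(config.quick_window_s * thermal.fs)))
            roi = forehead_roi(first_det)
            t_ir = float(
                np.mean([
                    mean_roi_temperature(thermal.frames[i], roi, config.roi_stat)
                    for i in range(n_quick)
                ])
            )
            t_comp = compensate_temperature(t_ir, ambient, d_m, calibration)
            fever = screen_fever(t_comp, config.fever_baseline_c, config.fever_margin_c)
            logger.info("stage=temperature t_ir=%.2f t_comp=%.2f d=%.2f", t_ir, t_comp, d_m)

            sig = extract_breath_signal(thermal, detections)
            if config.mode == "quick":
                est = _quick_rr(sig, config)
            else:
                est = rr_fft(sig, config.monitor_window_s)
                rr_series = _monitor_rr_series(sig, config)
            rr, rr_method, rr_window = est.rr_bpm, est.method, est.window_s
            tachypnea = est.tachypnea_flag
            if not est.determinate:
                reasons.append(f"rr_{est.reason}")
            logger.info("stage=respiration method=%s rr=%s", est.method, est.rr_bpm)

    if traces is None:
        reasons.append("no_channel_traces")
        logger.info("stage=pulse status=skipped reason=no_channel_traces")
    else:
        hr_est = estimate_hr_from_traces(traces, latency_s=config.hr_latency_s)
        hr, hr_latency, tachy = hr_est.hr_bpm, hr_est.latency_s, hr_est.tachycardia_flag
        if not hr_est.determinate:
            reasons.append(f"hr_{hr_est.reason}")
        logger.info("stage=pulse hr=%s", hr_est.hr_bpm)

    return VitalsReport(
        subject_id=subject_id,
        timestamp=ts,
        mode=config.mode,
        t_ir_c=t_ir,
        t_compensated_c=t_comp,
        fever_flag=fever,
        rr_bpm=rr,
        rr_method=rr_method,
        rr_window_s=rr_window,
        tachypnea_flag=tachypnea,
        hr_bpm=hr,
        hr_latency_s=hr_latency,
        tachycardia_flag=tachy,
        d_m=d_m,
        t_ambient_c=ambient.t_ambient_c,
        rr_series=tuple(rr_series),
        reasons=tuple(reasons),
    )


def write_report(report: VitalsReport, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2))
    if csv_path is not None:
        row = {k: v for k, v in report.to_dict().items() if k not in ("schema", "rr_series", "reasons")}
        row["reasons"] = ";".join(report.reasons)
        csv_path = Path(csv_path)
        df = pd.DataFrame([row])
        df.to_csv(csv_path, mode="a", header=not csv_path.exists(), index=False)


def read_report(json_path: str | Path) -> VitalsReport:
    return VitalsReport.from_dict(json.loads(Path(json_path).read_text()))
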