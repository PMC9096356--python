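"""Skin-temperature measurement with ambient/distance compensation.

An uncooled IR camera reads a forehead temperature that drifts with both the
subject's distance D and the ambient temperature: at each ambient level the
measured-vs-distance relationship is close to linear, and the (negative)
slope itself varies linearly with ambient temperature. Instead of a black-body
reference held at fixed distance, the bias is modelled parametrically and
subtracted:

    T_compensated = T_IR - (a * T_ambient + b) * (D + c) + d

with ``slope(T_ambient) = a * T_ambient + b`` in °C per metre, ``c`` an
additive distance shift in metres and ``d`` a global offset in °C. With all
parameters zero the compensation is the identity. The calibration is fitted
from (T_IR, reference temperature, T_ambient, D) samples by two stages of
ordinary least squares: bias-vs-distance per ambient level, then
slope-vs-ambient across levels.

Fever screening compares the compensated temperature against a population
baseline plus a margin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import ROI

__all__ = [
    "AmbientConditions",
    "ThermalCalibration",
    "TemperatureReading",
    "ThermalCompensationModel",
    "ThermalCalibrationResults",
    "mean_roi_temperature",
    "compensate_temperature",
    "fit_calibration",
    "screen_fever",
    "baseline_from_cohort",
    "CALIBRATED_DISTANCE_RANGE_M",
    "DEFAULT_FEVER_MARGIN_C",
]

#: Distance range over which the bias model is calibrated; outside it the
#: compensation extrapolates (with a warning).
CALIBRATED_DISTANCE_RANGE_M = (0.5, 5.0)

DEFAULT_FEVER_MARGIN_C = 0.5


@dataclass(frozen=True)
class AmbientConditions:
    """Ambient temperature (°C) and pressure/vapour pressure (kPa)."""

    t_ambient_c: float
    p_a_kpa: float = 101.3

    def __post_init__(self) -> None:
        if not (-20 < self.t_ambient_c < 50):
            raise ValueError(f"ambient temperature {self.t_ambient_c} °C out of range (-20, 50)")
        if not (0 < self.p_a_kpa < 110):
            raise ValueError(f"ambient pressure {self.p_a_kpa} kPa out of range (0, 110)")


@dataclass(frozen=True)
class ThermalCalibration:
    """Parameters of the distance/ambient thermal-bias model.

    bias(T_ambient, D) = (slope_a * T_ambient + slope_b) * (D + distance_offset_m)
                         - offset_d_c

    so that ``T_compensated = T_IR - bias``. Units: slope in °C/m (slope_a in
    °C·m⁻¹·°C⁻¹), distance offset in metres, offset_d in °C.
    """

    slope_a: float
    slope_b: float
    distance_offset_m: float = 0.0
    offset_d_c: float = 0.0
    r2: dict | None = None
    fitted_on: int | None = None

    def slope(self, t_ambient_c: float) -> float:
        """Bias slope (°C per metre) at a given ambient temperature."""
        return self.slope_a * t_ambient_c + self.slope_b

    def bias(self, t_ambient_c: float, d_m: float) -> float:
        return self.slope(t_ambient_c) * (d_m + self.distance_offset_m) - self.offset_d_c

    @classmethod
    def identity(cls) -> "ThermalCalibration":
        """All-zero calibration: compensation becomes the identity map."""
        return cls(0.0, 0.0, 0.0, 0.0)

    @classmethod
    def reported_constants(cls) -> "ThermalCalibration":
        """A previously reported parameterisation of this bias family.

        Its printed constants are typographically unreliable (slope
        (T_ambient − 31)/1900 °C per *millimetre*, distance shift 3000 mm,
        offset −0.17 °C); they are kept here, converted to metre units, for
        reference only. Prefer a refitted calibration for real use.
        """
        return cls(slope_a=1.0 / 1.9, slope_b=-31.0 / 1.9,
                   distance_offset_m=3.0, offset_d_c=-0.17)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "vitalcam.calibration.v1",
            "slope_a": self.slope_a,
            "slope_b": self.slope_b,
            "distance_offset_m": self.distance_offset_m,
            "offset_d_c": self.offset_d_c,
            "r2": self.r2,
            "fitted_on": self.fitted_on,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThermalCalibration":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "vitalcam.calibration.v1":
            raise ValueError(f"unrecognised calibration schema: {payload.get('schema')!r}")
        return cls(
            slope_a=payload["slope_a"],
            slope_b=payload["slope_b"],
            distance_offset_m=payload["distance_offset_m"],
            offset_d_c=payload["offset_d_c"],
            r2=payload.get("r2"),
            fitted_on=payload.get("fitted_on"),
        )


@dataclass(frozen=True)
class TemperatureReading:
    """One compensated forehead reading plus the context it was taken in."""

    t_ir_c: float
    t_compensated_c: float
    d_m: float
    t_ambient_c: float
    fever_flag: bool


def mean_roi_temperature(
    frame: np.ndarray,
    roi: ROI,
    stat: Literal["mean", "max", "p95"] = "mean",
) -> float:
    """Summary temperature (°C) of an ROI in a 2-D temperature grid."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D temperature grid")
    if not roi.within(frame.shape):
        raise ValueError(f"ROI {roi} outside frame of shape {frame.shape}")
    pixels = frame[roi.slices()]
    if stat == "mean":
        return float(pixels.mean())
    if stat == "max":
        return float(pixels.max())
    if stat == "p95":
        return float(np.percentile(pixels, 95))
    raise ValueError(f"unknown ROI statistic {stat!r}")


def compensate_temperature(
    t_ir_c: float,
    ambient: AmbientConditions,
    d_m: float,
    calib: ThermalCalibration,
) -> float:
    """Remove the fitted distance/ambient bias from an IR reading.

    Affine in ``t_ir_c`` with unit coefficient; the identity when the
    calibration is all-zero. Distances outside the calibrated range are
    extrapolated with a warning.
    """
    if d_m <= 0:
        raise ValueError("distance must be positive")
    lo, hi = CALIBRATED_DISTANCE_RANGE_M
    if not (lo <= d_m <= hi):
        warnings.warn(
            f"distance {d_m:.2f} m outside calibrated range [{lo}, {hi}] m; extrapolating",
            stacklevel=2,
        )
    return float(t_ir_c - calib.bias(ambient.t_ambient_c, d_m))


# ---------------------------------------------------------------------------
# Calibration fitting
# ---------------------------------------------------------------------------

class ThermalCompensationModel:
    """Two-stage OLS model of the IR thermal bias.

    Built from calibration samples ``(t_ir, true_temp, t_ambient, d_m)``.
    Stage 1 regresses the bias ``t_ir - true_temp`` on distance within each
    ambient level; stage 2 regresses the per-level slopes on ambient
    temperature, and the per-level intercepts on the slopes to recover the
    distance shift ``c`` and global offset ``d`` (intercept_k = slope_k·c − d).

    Ambient levels are grouped by rounding to 0.01 °C; the design needs at
    least two levels and at least two distinct distances within each level.
    """

    def __init__(self, samples: Sequence[tuple[float, float, float, float]]):
        arr = np.asarray(samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 4:
            raise ValueError(
                "samples must be an (n >= 4) x 4 array of (t_ir, true_temp, t_ambient, d_m)"
            )
        self.t_ir = arr[:, 0]
        self.true_temp = arr[:, 1]
        self.t_ambient = arr[:, 2]
        self.d_m = arr[:, 3]
        self.bias = self.t_ir - self.true_temp

    @classmethod
    def from_dataframe(cls, df) -> "ThermalCompensationModel":
        """Build from a DataFrame with columns t_ir, true_temp, t_ambient, d_m."""
        cols = ["t_ir", "true_temp", "t_ambient", "d_m"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        return cls(df[cols].to_numpy())

    def fit(self) -> "ThermalCalibrationResults":
        levels = np.unique(np.round(self.t_ambient, 2))
        if levels.size < 2:
            raise ValueError(
                "calibration design is rank deficient: need >= 2 ambient-temperature "
                f"levels, got {levels.size}"
            )
        slopes, intercepts, level_r2 = [], [], {}
        for lev in levels:
            sel = np.isclose(np.round(self.t_ambient, 2), lev)
            d, b = self.d_m[sel], self.bias[sel]
            if np.unique(d).size < 2:
                raise ValueError(
                    "calibration design is rank deficient: need >= 2 distinct distances "
                    f"at ambient level {lev} °C"
                )
            coef, res = _ols_line(d, b)
            slopes.append(coef[0])
            intercepts.append(coef[1])
            level_r2[float(lev)] = res
        slopes = np.asarray(slopes)
        intercepts = np.asarray(intercepts)

        (a, b), r2_slope = _ols_line(levels, slopes)
        if np.ptp(slopes) < 1e-14:
            # degenerate: slope independent of ambient; c unidentifiable, take 0
            c, neg_d, r2_off = 0.0, float(intercepts.mean()), 1.0
        else:
            (c, neg_d), r2_off = _ols_line(slopes, intercepts)
        calib = ThermalCalibration(
            slope_a=float(a),
            slope_b=float(b),
            distance_offset_m=float(c),
            offset_d_c=float(-neg_d),
            r2={"per_ambient": level_r2, "slope_vs_ambient": r2_slope, "offsets": r2_off},
            fitted_on=int(self.t_ir.size),
        )
        return ThermalCalibrationResults(self, calib)


@dataclass(frozen=True)
class ThermalCalibrationResults:
    """Fitted thermal-bias calibration with diagnostics."""

    model: ThermalCompensationModel
    calibration: ThermalCalibration

    @property
    def params(self) -> dict[str, float]:
        c = self.calibration
        return {
            "slope_a": c.slope_a,
            "slope_b": c.slope_b,
            "distance_offset_m": c.distance_offset_m,
            "offset_d_c": c.offset_d_c,
        }

    @property
    def resid(self) -> np.ndarray:
        """Residual bias after compensation, per calibration sample (°C)."""
        m, c = self.model, self.calibration
        predicted = np.array([c.bias(t, d) for t, d in zip(m.t_ambient, m.d_m)])
        return m.bias - predicted

    @property
    def mae(self) -> float:
        return float(np.abs(self.resid).mean())

    def compensate(self, t_ir_c: float, ambient: AmbientConditions, d_m: float) -> float:
        return compensate_temperature(t_ir_c, ambient, d_m, self.calibration)

    def summary(self) -> str:
        c = self.calibration
        lines = [
            "Thermal bias calibration (two-stage OLS)",
            "=" * 44,
            f"n samples          : {self.model.t_ir.size}",
            f"slope_a            : {c.slope_a: .5f} °C m⁻¹ °C⁻¹",
            f"slope_b            : {c.slope_b: .5f} °C m⁻¹",
            f"distance offset c  : {c.distance_offset_m: .4f} m",
            f"global offset d    : {c.offset_d_c: .4f} °C",
            f"residual MAE       : {self.mae: .4f} °C",
            f"R² slope-vs-ambient: {c.r2['slope_vs_ambient']: .4f}" if c.r2 else "",
        ]
        return "\n".join(filter(None, lines))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    """Least-squares line fit; returns ((slope, intercept), R^2)."""
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return (float(slope), float(intercept)), r2


def fit_calibration(
    samples: Sequence[tuple[float, float, float, float]]
) -> ThermalCalibration:
    """Fit the bias calibration from (t_ir, true_temp, t_ambient, d_m) samples."""
    return ThermalCompensationModel(samples).fit().calibration


# ---------------------------------------------------------------------------
# Fever screening
# ---------------------------------------------------------------------------

def baseline_from_cohort(temperatures_c: Iterable[float]) -> float:
    """Population baseline: mean compensated skin temperature of a healthy cohort."""
    temps = np.asarray(list(temperatures_c), dtype=float)
    if temps.size == 0:
        raise ValueError("cohort is empty")
    return float(temps.mean())


def screen_fever(
    t_compensated_c: float,
    baseline_c: float,
    margin_c: float = DEFAULT_FEVER_MARGIN_C,
) -> bool:
    """Flag elevated skin temperature: strictly above baseline + margin."""
    return t_compensated_c > baseline_c + margin_c
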