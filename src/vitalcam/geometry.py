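"""Facial ROI construction and monocular distance estimation.

All downstream vital-sign estimators work on two rectangular regions of
interest derived from a face bounding box and the eye landmark line:

* the **forehead ROI** (box top edge down to the eye line) — used for skin
  temperature and for the tri-channel reflectance traces feeding heart-rate
  estimation;
* the **mask ROI** (lower half of the box, trimmed 10 % on each side) —
  used for the thermal breathing signal of a facemask wearer.

Subject distance is recovered from the face-box diagonal through an
empirical power law ``D = k * L**(-p)`` (default ``k = 140.22``,
``p = 1.14``, metres vs. pixels), with the diagonal first corrected for
head pitch/yaw foreshortening.

Pixel conventions: 0-based coordinates, origin top-left, y increases
downward; ROIs are half-open rectangles ``[x0, x1) x [y0, y1)``.
Fractional ROI bounds are rounded half-away-from-zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "FaceDetection",
    "ROI",
    "DistanceEstimate",
    "forehead_roi",
    "mask_roi",
    "corrected_diagonal",
    "distance_from_diagonal",
    "diagonal_from_distance",
    "estimate_distance",
    "fit_distance_law",
    "detections_to_json",
    "detections_from_json",
    "DISTANCE_COEF",
    "DISTANCE_EXPONENT",
]

#: Default constants of the distance power law D = COEF * L**(-EXPONENT)
#: (D in metres, L the pose-corrected face-box diagonal in pixels).
DISTANCE_COEF = 140.22
DISTANCE_EXPONENT = 1.14

# Mask-ROI fractions of the bounding box: x in [0.1 w, 0.9 w], y in [0.5 h, h].
_MASK_X_LO = 0.1
_MASK_X_HI = 0.9
_MASK_Y_LO = 0.5


def _round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned face bounding box, top-left anchored, in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"bounding box must have positive size, got w={self.w}, h={self.h}")

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    @property
    def diagonal(self) -> float:
        """Raw (pose-uncorrected) diagonal length in pixels."""
        return math.hypot(self.w, self.h)


@dataclass(frozen=True)
class FaceDetection:
    """One frame's face detection: box, eye line and head pose.

    ``y_eye`` is the y coordinate of the eye landmarks; it must fall strictly
    inside the box. Pose angles are in degrees, magnitudes below 90.
    """

    box: BoundingBox
    y_eye: float
    pitch_deg: float = 0.0
    yaw_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.box.y < self.y_eye < self.box.y1):
            raise ValueError(
                f"eye line y={self.y_eye} must lie strictly inside the box "
                f"[{self.box.y}, {self.box.y1}]"
            )
        if abs(self.pitch_deg) >= 90 or abs(self.yaw_deg) >= 90:
            raise ValueError("pose angles must satisfy |pitch|, |yaw| < 90 degrees")


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate ROI ({self.x0},{self.y0})-({self.x1},{self.y1})")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices for indexing a frame array."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def within(self, frame_shape: tuple[int, int]) -> bool:
        nrow, ncol = frame_shape
        return self.x0 >= 0 and self.y0 >= 0 and self.x1 <= ncol and self.y1 <= nrow


@dataclass(frozen=True)
class DistanceEstimate:
    """Distance recovered from the face-box diagonal."""

    d_m: float
    l_px: float
    l_corrected_px: float


def forehead_roi(det: FaceDetection) -> ROI:
    """Forehead ROI: full box width, from the box top edge to the eye line."""
    b = det.box
    x0, y0 = _round_half_away(b.x), _round_half_away(b.y)
    x1, y1 = _round_half_away(b.x1), _round_half_away(det.y_eye)
    if y1 <= y0:
        raise ValueError("invalid landmarks: eye line does not leave room for a forehead ROI")
    return ROI(x0, y0, x1, y1)


def mask_roi(det: FaceDetection) -> ROI:
    """Facemask ROI: lower half of the box, trimmed 10 % on each side."""
    b = det.box
    x0 = _round_half_away(b.x + _MASK_X_LO * b.w)
    x1 = _round_half_away(b.x + _MASK_X_HI * b.w)
    y0 = _round_half_away(b.y + _MASK_Y_LO * b.h)
    y1 = _round_half_away(b.y1)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"bounding box {b.w:.0f}x{b.h:.0f} px too small for a mask ROI")
    return ROI(x0, y0, x1, y1)


def corrected_diagonal(det: FaceDetection) -> float:
    """Pose-corrected diagonal: root-sum-square of cos-corrected box extents.

    Head rotation foreshortens the apparent box, so width is divided by
    cos(yaw) and height by cos(pitch) before taking the diagonal. Reduces to
    the plain diagonal for a frontal face.
    """
    cy = math.cos(math.radians(det.yaw_deg))
    cp = math.cos(math.radians(det.pitch_deg))
    if cy <= 0 or cp <= 0:
        raise ValueError("pose angle at or beyond 90 degrees; diagonal undefined")
    return math.hypot(det.box.w / cy, det.box.h / cp)


def distance_from_diagonal(
    l_corrected_px: float,
    coef: float = DISTANCE_COEF,
    exponent: float = DISTANCE_EXPONENT,
) -> float:
    """Subject distance (m) from the pose-corrected diagonal via D = coef * L**(-exponent)."""
    if l_corrected_px <= 0:
        raise ValueError("diagonal length must be positive")
    return coef * l_corrected_px ** (-exponent)


def diagonal_from_distance(
    d_m: float,
    coef: float = DISTANCE_COEF,
    exponent: float = DISTANCE_EXPONENT,
) -> float:
    """Inverse of :func:`distance_from_diagonal`: L = (coef / D)**(1/exponent)."""
    if d_m <= 0:
        raise ValueError("distance must be positive")
    return (coef / d_m) ** (1.0 / exponent)


def estimate_distance(
    det: FaceDetection,
    coef: float = DISTANCE_COEF,
    exponent: float = DISTANCE_EXPONENT,
) -> DistanceEstimate:
    """Estimate subject distance from a detection, with pose correction."""
    l_raw = det.box.diagonal
    l_corr = corrected_diagonal(det)
    return DistanceEstimate(
        d_m=distance_from_diagonal(l_corr, coef, exponent),
        l_px=l_raw,
        l_corrected_px=l_corr,
    )


def fit_distance_law(
    diagonals_px: Sequence[float], distances_m: Sequence[float]
) -> tuple[float, float]:
    """Refit (coef, exponent) of the distance power law from (L, D) samples.

    Ordinary least squares on log D = log coef - exponent * log L.
    Requires at least two distinct diagonals.
    """
    L = np.asarray(diagonals_px, dtype=float)
    D = np.asarray(distances_m, dtype=float)
    if L.shape != D.shape or L.size < 2:
        raise ValueError("need at least two (diagonal, distance) pairs of equal length")
    if np.any(L <= 0) or np.any(D <= 0):
        raise ValueError("diagonals and distances must be positive")
    if np.allclose(L, L[0]):
        raise ValueError("diagonals are all identical; power law unidentifiable")
    slope, intercept = np.polyfit(np.log(L), np.log(D), 1)
    return float(np.exp(intercept)), float(-slope)


# ---------------------------------------------------------------------------
# JSON interchange for detection fixtures
# ---------------------------------------------------------------------------

def _det_to_record(frame: int, det: FaceDetection) -> dict:
    return {
        "frame": frame,
        "x": det.box.x,
        "y": det.box.y,
        "w": det.box.w,
        "h": det.box.h,
        "y_eye": det.y_eye,
        "pitch_deg": det.pitch_deg,
        "yaw_deg": det.yaw_deg,
    }


def detections_to_json(dets: Iterable[FaceDetection | None], path: str | Path) -> None:
    """Write per-frame detections as a JSON list; missing frames become null boxes."""
    records = []
    for i, det in enumerate(dets):
        records.append(None if det is None else _det_to_record(i, det))
    Path(path).write_text(json.dumps({"schema": "vitalcam.detections.v1", "detections": records}))


def detections_from_json(path: str | Path) -> list[FaceDetection | None]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "vitalcam.detections.v1":
        raise ValueError(f"unrecognised detections schema: {payload.get('schema')!r}")
    out: list[FaceDetection | None] = []
    for rec in payload["detections"]:
        if rec is None:
            out.append(None)
            continue
        known = {"frame", "x", "y", "w", "h", "y_eye", "pitch_deg", "yaw_deg"}
        unknown = set(rec) - known
        if unknown:
            raise ValueError(f"unknown detection field(s): {sorted(unknown)}")
        out.append(
            FaceDetection(
                box=BoundingBox(rec["x"], rec["y"], rec["w"], rec["h"]),
                y_eye=rec["y_eye"],
                pitch_deg=rec.get("pitch_deg", 0.0),
                yaw_deg=rec.get("yaw_deg", 0.0),
            )
        )
    return out
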