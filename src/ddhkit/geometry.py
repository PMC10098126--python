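"""Reference-line construction and hip-parameter measurement.

From the 8 annotated key points this module draws the classic diagnostic
constructs of the AP pelvic radiograph:

* Hilgenreiner's line (H-line) through the tops of the bilateral triradiate
  cartilages;
* per side, Perkin's line perpendicular to the H-line through the lateral
  acetabular edge, their junction, and the 45-degree diagonal line into the
  inferolateral quadrant;
* the H-point, midpoint of the inner and outer proximal-femoral-metaphysis
  points.

Every angle is measured in a per-side orthonormal frame (u lateral along
the H-line, v superior perpendicular to it) so that AI, LCEA, and the IHDI
grade are invariant under rigid motion and uniform scaling of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional, Tuple

import numpy as np

from .core import (
    AnnotationSet,
    DegenerateGeometryError,
    Landmark,
    Side,
    as_point,
)

__all__ = [
    "Line2D",
    "HipFrame",
    "HipSideGeometry",
    "ReferenceGeometry",
    "HeadCenterSource",
    "AngleMeasurement",
    "HipParameters",
    "build_reference_geometry",
    "measure_ai",
    "measure_lcea",
    "classify_ihdi",
    "ihdi_grade_from_offset",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Line2D:
    """A line through ``anchor`` with unit ``direction``."""

    anchor: Tuple[float, float]
    direction: Tuple[float, float]

    def __post_init__(self) -> None:
        d = as_point(self.direction)
        n = float(np.hypot(*d))
        if n == 0:
            raise DegenerateGeometryError("zero-length line direction")
        object.__setattr__(self, "anchor", tuple(as_point(self.anchor)))
        object.__setattr__(self, "direction", (float(d[0] / n), float(d[1] / n)))

    @property
    def anchor_arr(self) -> np.ndarray:
        return np.asarray(self.anchor)

    @property
    def direction_arr(self) -> np.ndarray:
        return np.asarray(self.direction)

    def project(self, p) -> np.ndarray:
        """Orthogonal projection of point ``p`` onto the line."""
        a, d = self.anchor_arr, self.direction_arr
        return a + float(np.dot(as_point(p) - a, d)) * d


@dataclass(frozen=True)
class HipFrame:
    """Per-side orthonormal frame at the Perkin-Hilgenreiner junction.

    ``u`` points laterally (along the H-line, away from the pelvic
    midline); ``v`` points superiorly (toward the ilium, i.e. negative
    image-y for an upright radiograph).
    """

    origin: Tuple[float, float]
    u: Tuple[float, float]
    v: Tuple[float, float]

    def to_frame(self, p) -> Tuple[float, float]:
        """Coordinates of point ``p`` in the (u, v) frame."""
        d = as_point(p) - np.asarray(self.origin)
        return float(np.dot(d, self.u)), float(np.dot(d, self.v))


@dataclass(frozen=True)
class HipSideGeometry:
    perkin_line: Line2D
    diagonal_line: Line2D
    junction: Tuple[float, float]
    frame: HipFrame
    h_point: Tuple[float, float]


@dataclass(frozen=True)
class ReferenceGeometry:
    h_line: Line2D
    sides: Dict[Side, HipSideGeometry]

    def side(self, side: Side) -> HipSideGeometry:
        return self.sides[side]


class HeadCenterSource(str, Enum):
    EXPLICIT = "explicit"
    H_POINT_PROXY = "h_point_proxy"


@dataclass(frozen=True)
class AngleMeasurement:
    value_deg: float
    warning: Optional[str] = None


@dataclass(frozen=True)
class HipParameters:
    """Measured AI and LCEA (degrees) for one hip."""

    ai_deg: float
    lcea_deg: Optional[float]
    head_center_source: HeadCenterSource
    warnings: Tuple[str, ...] = ()


def _superior_unit(dh: np.ndarray, toward: Optional[np.ndarray]) -> np.ndarray:
    """Unit vector perpendicular to the H-line direction pointing superiorly.

    "Superior" is anchored anatomically: the acetabular edge lies on the
    iliac side of the H-line, so v points into the half-plane containing
    ``toward`` (edge minus junction).  This keeps every angle and grade
    invariant under arbitrary rigid motion of the film.  Only when the edge
    sits exactly on the H-line does the image convention (negative y is up)
    decide.
    """
    cand = np.array([dh[1], -dh[0]])
    if toward is not None:
        norm = float(np.hypot(*toward))
        if norm > 0:
            side = float(np.dot(toward / norm, cand))
            if abs(side) > 1e-9:
                return cand if side > 0 else -cand
    if abs(cand[1]) > 1e-12:
        return cand if cand[1] < 0 else -cand
    return cand


def build_reference_geometry(annotations: AnnotationSet) -> ReferenceGeometry:
    """Construct the H-line and all per-side reference geometry.

    Requires the complete 8-landmark set.  Raises
    :class:`DegenerateGeometryError` if the two triradiate tops coincide.
    """
    annotations.require_complete()
    t_left = annotations.get(Landmark.TRIRADIATE_TOP, Side.LEFT)
    t_right = annotations.get(Landmark.TRIRADIATE_TOP, Side.RIGHT)
    sep = t_right - t_left
    if float(np.hypot(*sep)) < 1e-9:
        raise DegenerateGeometryError("triradiate tops coincide; H-line undefined")
    dh = sep / float(np.hypot(*sep))
    midline = (t_left + t_right) / 2.0
    h_line = Line2D(tuple(t_left), tuple(dh))

    sides: Dict[Side, HipSideGeometry] = {}
    for side in (Side.LEFT, Side.RIGHT):
        t = annotations.get(Landmark.TRIRADIATE_TOP, side)
        edge = annotations.get(Landmark.LATERAL_ACETABULAR_EDGE, side)
        inner = annotations.get(Landmark.METAPHYSIS_INNER, side)
        outer = annotations.get(Landmark.METAPHYSIS_OUTER, side)

        lateral = float(np.dot(t - midline, dh))
        if lateral == 0.0:
            lateral = float(np.dot(edge - midline, dh))
        if lateral == 0.0:
            raise DegenerateGeometryError(
                f"cannot orient lateral direction for side {side.value}"
            )
        u = dh if lateral > 0 else -dh

        junction = h_line.project(edge)
        v = _superior_unit(dh, toward=edge - junction)
        frame = HipFrame(tuple(junction), (float(u[0]), float(u[1])),
                         (float(v[0]), float(v[1])))
        perkin = Line2D(tuple(edge), (float(v[0]), float(v[1])))
        diag_dir = (u - v) / _SQRT2  # 45 deg into the inferolateral quadrant
        diagonal = Line2D(tuple(junction), (float(diag_dir[0]), float(diag_dir[1])))
        h_point = (inner + outer) / 2.0
        sides[side] = HipSideGeometry(
            perkin_line=perkin,
            diagonal_line=diagonal,
            junction=(float(junction[0]), float(junction[1])),
            frame=frame,
            h_point=(float(h_point[0]), float(h_point[1])),
        )
    return ReferenceGeometry(h_line=h_line, sides=sides)


def measure_ai(
    geometry: ReferenceGeometry, annotations: AnnotationSet, side: Side
) -> AngleMeasurement:
    """Acetabular index: angle between the H-line and the acetabular roof.

    The roof runs from the triradiate-cartilage top to the lateral
    acetabular edge; the angle is positive when the edge is superior to the
    H-line.  An edge medial to the triradiate top yields a warning flag
    (the value is still returned).
    """
    frame = geometry.side(side).frame
    t = annotations.get(Landmark.TRIRADIATE_TOP, side)
    edge = annotations.get(Landmark.LATERAL_ACETABULAR_EDGE, side)
    d = edge - t
    d_u = float(np.dot(d, frame.u))
    d_v = float(np.dot(d, frame.v))
    value = math.degrees(math.atan2(d_v, d_u))
    warning = None
    if d_u <= 0:
        warning = "acetabular edge is medial to the triradiate top"
    return AngleMeasurement(value, warning)


def measure_lcea(
    geometry: ReferenceGeometry,
    annotations: AnnotationSet,
    side: Side,
    head_center=None,
) -> Tuple[AngleMeasurement, HeadCenterSource]:
    """Lateral center-edge angle of Wiberg.

    The angle between the vertical through the femoral-head center and the
    line from that center to the lateral acetabular edge, positive when the
    edge is lateral to the vertical.  "Vertical" is perpendicular to the
    H-line, so the measurement is tilt-invariant.  When no explicit head
    center is supplied (ossification may make one unreliable in the study
    age range) the H-point serves as proxy, flagged in the returned source.
    """
    geo = geometry.side(side)
    if head_center is not None:
        c = as_point(head_center)
        source = HeadCenterSource.EXPLICIT
    else:
        c = np.asarray(geo.h_point)
        source = HeadCenterSource.H_POINT_PROXY
    edge = annotations.get(Landmark.LATERAL_ACETABULAR_EDGE, side)
    e = edge - c
    e_u = float(np.dot(e, geo.frame.u))
    e_v = float(np.dot(e, geo.frame.v))
    value = math.degrees(math.atan2(e_u, e_v))
    warning = None
    if e_v <= 0:
        warning = "acetabular edge at or below the head center"
    return AngleMeasurement(value, warning), source


def ihdi_grade_from_offset(p_u: float, p_v: float) -> int:
    """IHDI grade of an H-point at frame offset (p_u lateral, p_v superior).

    Grade 4: superior to the H-line.  Grade 1: at or medial to Perkin's
    line.  Grade 2: lateral to Perkin's line, at or medial to the diagonal.
    Grade 3: lateral to the diagonal, at or inferior to the H-line.  Ties
    ("at or ...") resolve to the lower grade.
    """
    if p_v > 0:
        return 4
    if p_u <= 0:
        return 1
    if p_u <= -p_v:
        return 2
    return 3


def classify_ihdi(geometry: ReferenceGeometry, side: Side) -> int:
    """IHDI grade (1-4) of the side's H-point."""
    geo = geometry.side(side)
    p_u, p_v = geo.frame.to_frame(geo.h_point)
    return ihdi_grade_from_offset(p_u, p_v)
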