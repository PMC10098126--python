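"""Shared domain types: landmarks, sides, annotation sets, and errors.

Coordinates follow image conventions throughout the package: ``x`` is the
column index (increasing rightward), ``y`` the row index (increasing
downward), both 0-based.  Annotation coordinates may be integer pixels
(fresh clicks, refined points) or real-valued (derived constructions);
geometric code promotes everything to floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np


class DdhkitError(Exception):
    """Base class for all package errors."""


class ValidationError(DdhkitError):
    """Malformed or contract-violating input (file, config, or argument)."""


class InvalidInputError(ValidationError):
    """An argument violates an operation precondition (e.g. point off-image)."""


class MissingLandmarkError(ValidationError):
    """A required landmark is absent from the annotation set."""


class DegenerateGeometryError(DdhkitError):
    """The annotated points do not define the reference construction."""


class CriteriaLookupError(DdhkitError):
    """No criteria-table entry covers the requested patient stratum."""


class UndefinedStatisticError(DdhkitError):
    """A statistic is undefined for the given data (zero denominator etc.)."""


class PhantomSpecError(ValidationError):
    """A phantom specification is infeasible or out of bounds."""


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Landmark(str, Enum):
    """The four per-side anatomical key points annotated by the user."""

    LATERAL_ACETABULAR_EDGE = "lateral_acetabular_edge"
    TRIRADIATE_TOP = "triradiate_top"
    METAPHYSIS_INNER = "metaphysis_inner"
    METAPHYSIS_OUTER = "metaphysis_outer"


LandmarkKey = Tuple[Landmark, Side]

#: All 8 (landmark, side) combinations of a complete study.
ALL_LANDMARKS: Tuple[LandmarkKey, ...] = tuple(
    (lm, side) for side in (Side.LEFT, Side.RIGHT) for lm in Landmark
)


def as_point(xy: Iterable[float]) -> np.ndarray:
    """Coerce an (x, y) pair to a float ndarray, checking finiteness."""
    p = np.asarray(tuple(xy), dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise InvalidInputError(f"not a finite (x, y) point: {xy!r}")
    return p


@dataclass(frozen=True)
class AnnotationSet:
    """The annotated key points of one radiograph, keyed by (landmark, side)."""

    points: Mapping[LandmarkKey, Tuple[float, float]]

    def __post_init__(self) -> None:
        norm: Dict[LandmarkKey, Tuple[float, float]] = {}
        for key, xy in self.points.items():
            lm, side = key
            if not isinstance(lm, Landmark) or not isinstance(side, Side):
                raise ValidationError(f"invalid landmark key: {key!r}")
            p = as_point(xy)
            norm[(lm, side)] = (float(p[0]), float(p[1]))
        object.__setattr__(self, "points", norm)

    def __contains__(self, key: LandmarkKey) -> bool:
        return key in self.points

    def __iter__(self) -> Iterator[LandmarkKey]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def get(self, landmark: Landmark, side: Side) -> np.ndarray:
        try:
            return np.asarray(self.points[(landmark, side)], dtype=float)
        except KeyError:
            raise MissingLandmarkError(
                f"missing landmark {landmark.value} ({side.value})"
            ) from None

    def with_point(
        self, landmark: Landmark, side: Side, xy: Iterable[float]
    ) -> "AnnotationSet":
        pts = dict(self.points)
        pts[(landmark, side)] = tuple(as_point(xy))
        return AnnotationSet(pts)

    def transformed(self, fn) -> "AnnotationSet":
        """Apply ``fn(point ndarray) -> point`` to every landmark."""
        return AnnotationSet(
            {k: tuple(as_point(fn(np.asarray(v)))) for k, v in self.points.items()}
        )

    @property
    def is_complete(self) -> bool:
        return all(k in self.points for k in ALL_LANDMARKS)

    def require_complete(self) -> None:
        for lm, side in ALL_LANDMARKS:
            if (lm, side) not in self.points:
                raise MissingLandmarkError(
                    f"missing landmark {lm.value} ({side.value})"
                )


def check_image(image: np.ndarray) -> np.ndarray:
    """Validate an 8-bit grayscale image array (H×W, uint8)."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D grayscale array")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise InvalidInputError("image must be 8-bit (values in [0, 255])")
    return arr


def check_point_in_image(point: Iterable[float], image: np.ndarray) -> np.ndarray:
    p = as_point(point)
    h, w = image.shape
    if not (0 <= p[0] < w and 0 <= p[1] < h):
        raise InvalidInputError(
            f"point ({p[0]:g}, {p[1]:g}) outside {w}x{h} image"
        )
    return p
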