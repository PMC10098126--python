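"""Edge-snapping rectification of annotated key points.

A user click that misses the bony rim is pulled onto it: a square window
around the click is smoothed (Gaussian), binarized with a local-mean
adaptive threshold (bone is radiodense, hence bright), and the boundary of
the thresholded foreground is taken as the rim.  The click snaps to the rim
pixel minimizing the Euclidean distance

    Ed = sqrt((x - a)^2 + (y - b)^2)

between the click (x, y) and candidate rim pixel (a, b).  Snapping is
integer-pixel and deterministic: ties are broken by smallest y, then
smallest x, and a guard distance prevents capture by distant structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Optional, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local

from .core import (
    AnnotationSet,
    InvalidInputError,
    LandmarkKey,
    ValidationError,
    check_image,
    check_point_in_image,
)

__all__ = [
    "RefinementConfig",
    "RefinementOutcome",
    "RefinementStatus",
    "binarize_window",
    "refine_point",
    "refine_annotations",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Tunable parameters of the window/threshold/snap procedure.

    ``window_size`` is the side of the square analysis window in pixels.
    The Gaussian prefilter and the local-mean adaptive threshold are both
    conventional small-window defaults; ``max_snap_distance`` rejects snaps
    to structures farther than a plausible click error.
    """

    window_size: int = 30
    gaussian_kernel: int = 5
    gaussian_sigma: float = 1.0
    adaptive_block: int = 11
    adaptive_offset: float = 2.0
    edge_min_gradient: float = 2.0
    max_snap_distance: float = 15.0
    #: landmarks eligible for refinement; None means all 8.
    enabled_labels: Optional[FrozenSet[LandmarkKey]] = None

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ValidationError("window_size must be >= 3")
        for name in ("gaussian_kernel", "adaptive_block"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValidationError(f"{name} must be odd and >= 3")
        if self.gaussian_sigma <= 0:
            raise ValidationError("gaussian_sigma must be > 0")
        if self.edge_min_gradient < 0:
            raise ValidationError("edge_min_gradient must be >= 0")
        if self.max_snap_distance <= 0:
            raise ValidationError("max_snap_distance must be > 0")

    def is_enabled(self, key: LandmarkKey) -> bool:
        return self.enabled_labels is None or key in self.enabled_labels


class RefinementOutcome(str, Enum):
    SNAPPED = "snapped"
    ALREADY_ON_EDGE = "already_on_edge"
    NO_EDGE_FOUND = "no_edge_found"
    BEYOND_MAX_DISTANCE = "beyond_max_distance"


@dataclass(frozen=True)
class RefinementStatus:
    outcome: RefinementOutcome
    snap_distance: Optional[float] = None


def _window_bounds(
    center: np.ndarray, shape: Tuple[int, int], window_size: int
) -> Tuple[int, int, int, int]:
    """Inclusive (x0, x1, y0, y1) of the clipped window around ``center``."""
    h, w = shape
    half = window_size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, x1 = max(0, cx - half), min(w - 1, cx + half)
    y0, y1 = max(0, cy - half), min(h - 1, cy + half)
    return x0, x1, y0, y1


def binarize_window(
    image: np.ndarray,
    center,
    config: RefinementConfig = RefinementConfig(),
) -> Set[Tuple[int, int]]:
    """Return the bony-rim pixels inside the window around ``center``.

    The window is Gaussian-filtered, thresholded against the local mean
    (foreground = intensity above local mean minus ``adaptive_offset``),
    and the candidate rim is the morphological boundary of the foreground:
    foreground pixels 4-adjacent to a background pixel inside the window.
    The edge-detection step then keeps only boundary pixels sitting on a
    real intensity edge (smoothed gradient magnitude above
    ``edge_min_gradient``); this rejects the band artifact a local-mean
    threshold produces on the dark side of a step and the speckle it
    produces in flat noisy regions.  Coordinates are absolute (x, y) image
    coordinates.
    """
    image = check_image(image)
    center = check_point_in_image(center, image)
    h, w = image.shape
    x0, x1, y0, y1 = _window_bounds(center, image.shape, config.window_size)

    # Filtering context comes from the image, not the window placement: the
    # window is extended by the filters' support before processing and the
    # result cropped back, so the detected rim depends only on the image.
    # Without this, padding effects near the window border would move the
    # rim between overlapping windows and break snap idempotence.
    radius = (config.gaussian_kernel - 1) // 2
    margin = radius + config.adaptive_block // 2 + 1
    ex0, ex1 = max(0, x0 - margin), min(w - 1, x1 + margin)
    ey0, ey1 = max(0, y0 - margin), min(h - 1, y1 + margin)
    win = image[ey0 : ey1 + 1, ex0 : ex1 + 1].astype(float)

    smoothed = ndimage.gaussian_filter(
        win, sigma=config.gaussian_sigma, truncate=radius / config.gaussian_sigma
    )
    block = min(config.adaptive_block, *_odd_caps(smoothed.shape))
    if block < 3 or smoothed.size < 9:
        return set()
    thresh = threshold_local(
        smoothed, block_size=block, method="mean", offset=config.adaptive_offset
    )
    fg = smoothed > thresh

    # Boundary: foreground 4-adjacent to background.  The image border is
    # not treated as background (border_value=1), so clipping never
    # manufactures an edge.
    interior = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    boundary = fg & ~interior
    if config.edge_min_gradient > 0:
        gy, gx = np.gradient(smoothed)
        boundary &= np.hypot(gx, gy) > config.edge_min_gradient
    boundary = boundary[y0 - ey0 : y1 - ey0 + 1, x0 - ex0 : x1 - ex0 + 1]
    rows, cols = np.nonzero(boundary)
    return {(int(c) + x0, int(r) + y0) for r, c in zip(rows, cols)}


def _odd_caps(shape: Tuple[int, int]) -> Tuple[int, int]:
    """Largest odd values not exceeding each window dimension."""
    return tuple(n if n % 2 == 1 else n - 1 for n in shape)


def refine_point(
    image: np.ndarray,
    point,
    config: RefinementConfig = RefinementConfig(),
) -> Tuple[Tuple[int, int], RefinementStatus]:
    """Snap ``point`` to the nearest rim pixel in its window.

    Returns the (possibly unchanged) integer pixel point and a status.  The
    minimizer of Ed is unique by the documented tie-break (smallest y, then
    smallest x), so the operation is deterministic and idempotent.
    """
    image = check_image(image)
    p = check_point_in_image(point, image)
    px, py = int(round(p[0])), int(round(p[1]))
    edges = binarize_window(image, (px, py), config)
    if not edges:
        return (px, py), RefinementStatus(RefinementOutcome.NO_EDGE_FOUND)

    best = min(
        edges,
        key=lambda ab: (math.hypot(px - ab[0], py - ab[1]), ab[1], ab[0]),
    )
    dist = math.hypot(px - best[0], py - best[1])
    if dist == 0.0:
        return (px, py), RefinementStatus(RefinementOutcome.ALREADY_ON_EDGE, 0.0)
    if dist > config.max_snap_distance:
        return (px, py), RefinementStatus(RefinementOutcome.BEYOND_MAX_DISTANCE)
    return best, RefinementStatus(RefinementOutcome.SNAPPED, dist)


def refine_annotations(
    image: np.ndarray,
    annotations: AnnotationSet,
    config: RefinementConfig = RefinementConfig(),
) -> Tuple[AnnotationSet, Dict[LandmarkKey, RefinementStatus]]:
    """Apply :func:`refine_point` to every enabled landmark.

    Landmarks outside ``config.enabled_labels`` pass through unchanged and
    receive no status.  Errors are annotated with the offending label.
    """
    out = dict(annotations.points)
    statuses: Dict[LandmarkKey, RefinementStatus] = {}
    for key, xy in annotations.points.items():
        if not config.is_enabled(key):
            continue
        try:
            snapped, status = refine_point(image, xy, config)
        except InvalidInputError as exc:
            lm, side = key
            raise InvalidInputError(
                f"{lm.value} ({side.value}): {exc}"
            ) from exc
        out[key] = (float(snapped[0]), float(snapped[1]))
        statuses[key] = status
    return AnnotationSet(out), statuses
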