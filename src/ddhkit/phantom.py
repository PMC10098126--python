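"""Synthetic AP-pelvis phantoms with exact landmark ground truth.

The phantoms are stylized, not anatomical: each hemipelvis is a bright
ilium polygon whose inferior edge is the acetabular roof (drawn at exactly
the requested acetabular index against the H-line), and each femur is a
bright metaphysis quadrilateral whose superior edge is centred on the
requested H-point offset, plus an optional femoral-head disk.  What matters
for testing is that (a) the geometry is analytically known, so AI, LCEA and
IHDI grade have exact ground truth, and (b) bone/background edges are sharp
and snappable, so annotation jitter and rim rectification can be exercised.
Seeded Gaussian noise stands in for radiographic noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import disk, polygon

from .core import AnnotationSet, Landmark, PhantomSpecError, Side
from .diagnose import Nationality, PatientInfo, Sex
from .geometry import ihdi_grade_from_offset

__all__ = [
    "PhantomHipSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomStudy",
    "make_phantom",
    "jitter_annotations",
    "phantom_batch",
    "BATCH_CLASSES",
]

#: Margins keeping sampled ground truth unambiguous under pixel rounding.
AI_MARGIN_DEG = 1.0
OFFSET_MARGIN_PX = 2.0


@dataclass(frozen=True)
class PhantomHipSpec:
    """Ground-truth parameters of one hip.

    ``ai_deg`` is the acetabular index of the rendered roof;
    ``h_point_offset`` is the H-point position relative to the
    Perkin-Hilgenreiner junction in (lateral, superior) pixels — medial
    offsets are negative in the first component, infra-H-line positions
    negative in the second.
    """

    ai_deg: float = 22.0
    h_point_offset: Tuple[float, float] = (-20.0, -40.0)
    roof_length: float = 120.0
    metaphysis_width: float = 36.0
    head_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.roof_length <= 0 or self.metaphysis_width <= 0:
            raise PhantomSpecError("roof_length and metaphysis_width must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    width: int = 640
    height: int = 480
    midline_x: float = 320.0
    hline_y: float = 260.0
    hline_tilt_deg: float = 0.0
    tri_half_spacing: float = 90.0
    left: PhantomHipSpec = field(default_factory=PhantomHipSpec)
    right: PhantomHipSpec = field(default_factory=PhantomHipSpec)
    bone_intensity: int = 200
    background_intensity: int = 40
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bone_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise PhantomSpecError(f"{name} must be in [0, 255]")
        if self.bone_intensity <= self.background_intensity:
            raise PhantomSpecError("bone must be brighter than background")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if self.tri_half_spacing <= 0:
            raise PhantomSpecError("tri_half_spacing must be > 0")

    def hip(self, side: Side) -> PhantomHipSpec:
        return self.left if side is Side.LEFT else self.right


@dataclass(frozen=True)
class PhantomTruth:
    """Exact pre-noise ground truth of a rendered phantom."""

    annotations: AnnotationSet  # exact (continuous) landmark coordinates
    ai_deg: Dict[Side, float]
    ihdi_grade: Dict[Side, int]
    h_point: Dict[Side, Tuple[float, float]]


def _hip_geometry(spec: PhantomSpec, side: Side) -> Dict[str, np.ndarray]:
    """Analytic landmark positions (continuous coordinates) for one side."""
    hip = spec.hip(side)
    tilt = math.radians(spec.hline_tilt_deg)
    dh = np.array([math.cos(tilt), math.sin(tilt)])  # along H-line, rightward
    v = np.array([dh[1], -dh[0]])  # superior (negative y at zero tilt)
    if v[1] > 0:
        v = -v
    u = dh if side is Side.RIGHT else -dh  # lateral: away from midline
    center = np.array([spec.midline_x, spec.hline_y])

    tri = center + spec.tri_half_spacing * u
    ai = math.radians(hip.ai_deg)
    edge = tri + hip.roof_length * (math.cos(ai) * u + math.sin(ai) * v)
    junction = center + float(np.dot(edge - center, dh)) * dh
    pu, pv = hip.h_point_offset
    h_point = junction + pu * u + pv * v
    half_w = hip.metaphysis_width / 2.0
    inner = h_point - half_w * u
    outer = h_point + half_w * u
    return {
        "u": u,
        "v": v,
        "tri": tri,
        "edge": edge,
        "junction": junction,
        "h_point": h_point,
        "inner": inner,
        "outer": outer,
    }


def _fill_polygon(canvas: np.ndarray, pts: Sequence[np.ndarray], value: int) -> None:
    arr = np.asarray(pts, dtype=float)
    rr, cc = polygon(arr[:, 1], arr[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value


def make_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, PhantomTruth]:
    """Render a phantom radiograph and return it with its ground truth.

    The returned annotations are the exact pre-noise landmark coordinates
    (continuous, not rounded to the pixel grid); re-measuring on them
    recovers the specified AI and IHDI grade exactly up to float error,
    provided the spec keeps the H-point offset away from grade boundaries.
    Rendering quantization only enters once clicks are simulated by
    :func:`jitter_annotations` or re-snapped from the image.
    """
    canvas = np.full(
        (spec.height, spec.width), spec.background_intensity, dtype=float
    )
    ann: Dict[Tuple[Landmark, Side], Tuple[float, float]] = {}
    truth_ai: Dict[Side, float] = {}
    truth_grade: Dict[Side, int] = {}
    truth_h: Dict[Side, Tuple[float, float]] = {}

    for side in (Side.LEFT, Side.RIGHT):
        g = _hip_geometry(spec, side)
        hip = spec.hip(side)
        u, v = g["u"], g["v"]

        landmarks = {
            Landmark.TRIRADIATE_TOP: g["tri"],
            Landmark.LATERAL_ACETABULAR_EDGE: g["edge"],
            Landmark.METAPHYSIS_INNER: g["inner"],
            Landmark.METAPHYSIS_OUTER: g["outer"],
        }
        for lm, p in landmarks.items():
            if not (0 <= p[0] < spec.width and 0 <= p[1] < spec.height):
                raise PhantomSpecError(
                    f"{lm.value} ({side.value}) at ({p[0]:.1f}, {p[1]:.1f}) "
                    f"is outside the {spec.width}x{spec.height} image"
                )
            ann[(lm, side)] = (float(p[0]), float(p[1]))

        # Ilium: polygon sitting on the roof segment tri->edge, extending
        # superiorly; tri and edge are corners on the bone boundary.
        ilium = [
            g["tri"],
            g["edge"],
            g["edge"] + 60.0 * v + 10.0 * u,
            g["tri"] + 60.0 * v - 10.0 * u,
        ]
        _fill_polygon(canvas, ilium, spec.bone_intensity)

        # Metaphysis: quadrilateral whose superior edge is inner->outer,
        # shaft extending inferiorly with a slight medial taper.
        shaft = 55.0
        meta = [
            g["inner"],
            g["outer"],
            g["outer"] - shaft * v - 4.0 * u,
            g["inner"] - shaft * v + 4.0 * u,
        ]
        _fill_polygon(canvas, meta, spec.bone_intensity)

        if hip.head_radius is not None:
            rr, cc = disk(
                (g["h_point"][1], g["h_point"][0]),
                hip.head_radius,
                shape=canvas.shape,
            )
            canvas[rr, cc] = spec.bone_intensity

        truth_ai[side] = hip.ai_deg
        truth_grade[side] = ihdi_grade_from_offset(*hip.h_point_offset)
        truth_h[side] = (float(g["h_point"][0]), float(g["h_point"][1]))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = PhantomTruth(
        annotations=AnnotationSet(ann),
        ai_deg=truth_ai,
        ihdi_grade=truth_grade,
        h_point=truth_h,
    )
    return image, truth


def jitter_annotations(
    annotations: AnnotationSet,
    sigma: float,
    seed: int,
    bounds: Optional[Tuple[int, int]] = None,
) -> AnnotationSet:
    """Add round-to-integer Gaussian click noise (sd ``sigma``) to every landmark.

    ``bounds`` = (width, height) clamps displaced points to the image.
    Reproducible for a fixed seed; landmarks are perturbed in a fixed
    (sorted-key) order so the output is independent of dict ordering.
    """
    if sigma < 0:
        raise PhantomSpecError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[Landmark, Side], Tuple[float, float]] = {}
    for key in sorted(annotations.points, key=lambda k: (k[0].value, k[1].value)):
        x, y = annotations.points[key]
        if sigma > 0:
            dx, dy = np.rint(rng.normal(0.0, sigma, 2))
            x, y = x + dx, y + dy
        if bounds is not None:
            w, h = bounds
            x = min(max(x, 0.0), w - 1.0)
            y = min(max(y, 0.0), h - 1.0)
        out[key] = (float(x), float(y))
    return AnnotationSet(out)


#: Severity classes a batch can mix.
BATCH_CLASSES = ("normal", "ddh1", "ddh2", "ddh3", "ddh4", "other")

#: Default per-class AI ranges (degrees) for a normal threshold of 31 deg
#: (mean 23, SD 4), honouring the 1-degree boundary margin.
DEFAULT_AI_RANGES: Dict[str, Tuple[float, float]] = {
    "normal": (15.0, 29.5),
    "other": (15.0, 29.5),
    "ddh1": (32.5, 40.0),
    "ddh2": (32.5, 40.0),
    "ddh3": (32.5, 40.0),
    "ddh4": (32.5, 40.0),
}


@dataclass(frozen=True)
class PhantomStudy:
    image: np.ndarray
    truth: PhantomTruth
    patient: PatientInfo
    spec: PhantomSpec
    class_label: str
    expected_category: Dict[Side, str]


def _sample_offset(rng: np.random.Generator, grade: int) -> Tuple[float, float]:
    """H-point offset uniformly inside the grade's region, >= 4 px from
    every boundary (2 px spec margin doubled to survive integer rounding of
    the metaphysis endpoints and junction)."""
    m = 4.0
    if grade == 1:
        return (float(rng.uniform(-45, -m)), float(rng.uniform(-60, -25)))
    if grade == 2:
        pv = float(rng.uniform(-60, -3 * m))
        pu = float(rng.uniform(m, -pv - m))
        return (pu, pv)
    if grade == 3:
        pv = float(rng.uniform(-28, -m))
        pu = float(rng.uniform(-pv + m, 70))
        return (pu, pv)
    if grade == 4:
        return (float(rng.uniform(15, 60)), float(rng.uniform(m, 22)))
    raise PhantomSpecError(f"no such grade: {grade}")


_CLASS_GRADE = {"normal": 1, "ddh1": 1, "ddh2": 2, "ddh3": 3, "ddh4": 4, "other": 3}
_CLASS_CATEGORY = {
    "normal": "normal",
    "other": "other_dislocation",
    "ddh1": "ddh",
    "ddh2": "ddh",
    "ddh3": "ddh",
    "ddh4": "ddh",
}


def phantom_batch(
    n: int,
    grade_mix: Dict[str, float],
    *,
    ai_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    patient: Optional[PatientInfo] = None,
    noise_sd: float = 3.0,
) -> List[PhantomStudy]:
    """Sample ``n`` phantom studies from a severity-class mixture.

    Each study draws one class (both hips share it; hip parameters are
    sampled independently within the class), an AI uniform in the class's
    range, and an H-point offset inside the class's IHDI region with a
    rounding-safe margin, so every truth label is unambiguous.  All
    randomness flows from ``seed``.
    """
    if n < 0:
        raise PhantomSpecError("n must be >= 0")
    labels = list(grade_mix)
    probs = np.asarray([grade_mix[c] for c in labels], dtype=float)
    if labels and not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
        raise PhantomSpecError("grade_mix probabilities must sum to 1")
    for c in labels:
        if c not in BATCH_CLASSES:
            raise PhantomSpecError(f"unknown class {c!r}")
    ranges = dict(DEFAULT_AI_RANGES)
    if ai_ranges:
        ranges.update(ai_ranges)
    for c in labels:
        lo, hi = ranges[c]
        if hi <= lo:
            raise PhantomSpecError(f"empty AI range for class {c!r}")
    if patient is None:
        patient = PatientInfo(Nationality.CHINESE, Sex.FEMALE, 2.0)

    rng = np.random.default_rng(seed)
    studies: List[PhantomStudy] = []
    for _ in range(n):
        cls = labels[int(rng.choice(len(labels), p=probs))]
        hips = {}
        for side in (Side.LEFT, Side.RIGHT):
            lo, hi = ranges[cls]
            hips[side] = PhantomHipSpec(
                ai_deg=float(rng.uniform(lo, hi)),
                h_point_offset=_sample_offset(rng, _CLASS_GRADE[cls]),
            )
        spec = PhantomSpec(
            left=hips[Side.LEFT],
            right=hips[Side.RIGHT],
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = make_phantom(spec)
        studies.append(
            PhantomStudy(
                image=image,
                truth=truth,
                patient=patient,
                spec=spec,
                class_label=cls,
                expected_category={
                    Side.LEFT: _CLASS_CATEGORY[cls],
                    Side.RIGHT: _CLASS_CATEGORY[cls],
                },
            )
        )
    return studies
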