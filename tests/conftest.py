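import numpy as np
import pytest

import ddhkit as dk
from ddhkit.io import default_criteria_table


@pytest.fixture
def step_image():
    """Vertical intensity step: dark (30) for x < 40, bright (220) for x >= 40."""
    img = np.zeros((100, 100), np.uint8)
    img[:, :40] = 30
    img[:, 40:] = 220
    return img


@pytest.fixture
def uniform_image():
    return np.full((100, 100), 100, np.uint8)


@pytest.fixture
def axis_annotations():
    """Hand-constructed symmetric study with a horizontal H-line at y=200,
    midline x=200; right lateral edge 40 px lateral / 20 px superior of the
    triradiate top (AI = atan2(20, 40) = 26.57 deg)."""
    L, S = dk.Landmark, dk.Side
    return dk.AnnotationSet({
        (L.TRIRADIATE_TOP, S.LEFT): (100, 200),
        (L.TRIRADIATE_TOP, S.RIGHT): (300, 200),
        (L.LATERAL_ACETABULAR_EDGE, S.LEFT): (60, 180),
        (L.LATERAL_ACETABULAR_EDGE, S.RIGHT): (340, 180),
        (L.METAPHYSIS_INNER, S.LEFT): (80, 225),
        (L.METAPHYSIS_OUTER, S.LEFT): (60, 235),
        (L.METAPHYSIS_INNER, S.RIGHT): (320, 225),
        (L.METAPHYSIS_OUTER, S.RIGHT): (340, 235),
    })


@pytest.fixture(scope="session")
def criteria_table():
    return default_criteria_table()


@pytest.fixture(scope="session")
def default_phantom():
    spec = dk.PhantomSpec(
        left=dk.PhantomHipSpec(ai_deg=25.0, h_point_offset=(-20, -40)),
        right=dk.PhantomHipSpec(ai_deg=35.0, h_point_offset=(30, -12)),
        seed=42,
    )
    image, truth = dk.make_phantom(spec)
    return spec, image, truth
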