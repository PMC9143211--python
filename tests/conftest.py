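"""Shared fixtures: phantoms with known geometry for every test module."""

from __future__ import annotations

import math

import numpy as np
import pytest

from orndose.core import BinaryVolume, ImageFrame
from orndose.synthetic_data import PhantomSpec, make_phantom
from orndose.volumetrics import mesh_from_mask, segment_bone

# condyle/angle-like protrusions (arch angle deg, z offset mm, radius mm):
# they break the arc's rotational and flip symmetries, as real anatomy does
LANDMARK_BUMPS = [(110, 8, 9), (-105, -9, 8), (40, -8, 7), (-30, 10, 7), (5, -9, 6)]


@pytest.fixture(scope="session")
def horseshoe_spec() -> PhantomSpec:
    return PhantomSpec(
        shape="horseshoe", arch_radius_mm=30.0, tube_radius_mm=9.0, arc_span_deg=240.0
    )


@pytest.fixture(scope="session")
def horseshoe_mask(horseshoe_spec) -> BinaryVolume:
    hu, frame, _ = make_phantom(horseshoe_spec, spacing_mm=1.5)
    return segment_bone(hu, frame, 300.0)


@pytest.fixture(scope="session")
def landmark_mask(horseshoe_spec) -> BinaryVolume:
    """Horseshoe with pronounced asymmetric bumps (condyles, angles)."""
    hu, frame, _ = make_phantom(horseshoe_spec, spacing_mm=1.5)
    x, y, z = frame.coordinate_grids()
    mask = hu > 300
    for ang_deg, dz, rb in LANDMARK_BUMPS:
        c = horseshoe_spec.arch_point(math.radians(ang_deg))
        ball = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2] - dz) ** 2 <= rb**2
        mask = mask | np.broadcast_to(ball, frame.shape)
    return BinaryVolume(frame=frame, mask=mask)


@pytest.fixture(scope="session")
def landmark_mesh(landmark_mask):
    return mesh_from_mask(landmark_mask)


@pytest.fixture()
def small_frame() -> ImageFrame:
    return ImageFrame(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), shape=(20, 20, 20))


def rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
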