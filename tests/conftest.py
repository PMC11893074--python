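"""Shared fixtures: small acquisition geometries and synthetic scenes.

Expensive rendered scenes are session-scoped so several test modules can
reuse them without re-rendering.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ulmkit import synthetic_ceus as sc
from ulmkit.core import AcquisitionConfig


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionConfig:
    """Small field of view, 2 s at 55 Hz (110 frames)."""
    return AcquisitionConfig(field_of_view=(32, 48), duration_s=2.0)


@pytest.fixture(scope="session")
def speckle() -> np.ndarray:
    """A smooth speckle texture with usable gradients for registration."""
    rng = np.random.default_rng(42)
    return ndimage.gaussian_filter(rng.rayleigh(1.0, (48, 64)), 1.0)


@pytest.fixture(scope="session")
def straight_segment() -> sc.VesselSegment:
    """A horizontal vessel crossing the small field of view."""
    return sc.VesselSegment(
        centerline_um=np.array([[120.0, 512.0], [1420.0, 512.0]]),
        diameter_um=20.0,
        peak_speed_mm_s=2.0,
    )


@pytest.fixture(scope="session")
def sparse_scene(acq_small, straight_segment) -> sc.VascScene:
    """Deterministic well-separated transits along one straight vessel."""
    return sc.simulate_regular_transits([straight_segment], 12, acq_small,
                                        seed=7)


@pytest.fixture(scope="session")
def sparse_rendered(sparse_scene):
    """(bmode, ceus) stacks for the sparse straight-vessel scene."""
    return sc.render_frames(sparse_scene)
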