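"""Morphometric readouts against analytic and constructed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulmkit import mapping as mp
from ulmkit import morphometrics as mm
from ulmkit.core import AcquisitionConfig, DegenerateInputError, Track
from ulmkit.mapping import ULMMaps


@pytest.fixture(scope="module")
def config():
    return AcquisitionConfig(field_of_view=(16, 24), duration_s=2.0)


def polyline_track(points, track_id=0):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    v = np.zeros((n, 2))
    return Track(track_id, np.arange(n), pts[:, 0], pts[:, 1],
                 v[:, 0], v[:, 1])


def make_maps(density=None, velocity=None, mask=None, fine_um=4.0):
    shape = next(
        a.shape for a in (density, velocity, mask) if a is not None
    )
    density = density if density is not None else np.ones(shape)
    velocity = velocity if velocity is not None else np.zeros(shape)
    mask = mask if mask is not None else (density > 0)
    return ULMMaps(density, velocity, np.zeros(shape), mask, fine_um)


class TestTortuosity:
    def test_collinear_is_one(self):
        assert mm.tortuosity(
            np.array([[0, 0], [100, 0], [200, 0]]), min_chord_um=1.0
        ) == pytest.approx(1.0)

    def test_right_angle(self):
        t = mm.tortuosity(
            np.array([[0, 0], [100, 0], [100, 100]]), min_chord_um=1.0
        )
        assert t == pytest.approx(2 / np.sqrt(2), rel=1e-9)  # ~1.41421

    def test_half_circle(self):
        theta = np.linspace(0, np.pi, 100)
        r = 500.0
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert mm.tortuosity(pts) == pytest.approx(np.pi / 2, abs=0.01)

    def test_rigid_motion_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        pts = np.cumsum(rng.normal(20, 5, size=(30, 2)), axis=0)
        base = mm.tortuosity(pts)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        moved = 3.0 * (pts @ rot.T) + np.array([123.0, -456.0])
        assert mm.tortuosity(moved) == pytest.approx(base, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        scale=st.floats(0.1, 10.0),
        tx=st.floats(-1e4, 1e4),
        ty=st.floats(-1e4, 1e4),
        seed=st.integers(0, 2**16),
    )
    def test_similarity_invariance_property(self, angle, scale, tx, ty,
                                            seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(20, 5, size=(12, 2)), axis=0)
        base = mm.tortuosity(pts, min_chord_um=1e-9)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = scale * (pts @ rot.T) + np.array([tx, ty])
        assert mm.tortuosity(moved, min_chord_um=1e-12) == pytest.approx(
            base, rel=1e-6
        )

    def test_near_closed_rejected(self):
        pts = np.array([[0, 0], [100, 0], [1.0, 0.5]])
        with pytest.raises(ValueError):
            mm.tortuosity(pts, min_chord_um=8.0)

    def test_mean_excludes_near_closed(self):
        good = polyline_track([[0, 0], [100, 0], [200, 0]], 0)
        closed = polyline_track([[0, 0], [100, 0], [1, 1]], 1)
        mean, values = mm.mean_tortuosity([good, closed])
        assert len(values) == 1
        assert mean == pytest.approx(1.0)


def sierpinski_carpet(order=4):
    mask = np.ones((3**order, 3**order), dtype=bool)
    for k in range(order):
        step = 3 ** (k + 1)
        third = 3**k
        for r0 in range(0, 3**order, step):
            for c0 in range(0, 3**order, step):
                mask[r0 + third:r0 + 2 * third,
                     c0 + third:c0 + 2 * third] = False
    return mask


class TestFractalDimension:
    def test_filled_square(self):
        assert mm.fractal_dimension(np.ones((256, 256), dtype=bool)) == (
            pytest.approx(2.0, abs=0.05)
        )

    def test_single_pixel_line(self):
        mask = np.zeros((256, 256), dtype=bool)
        mask[128, :] = True
        assert mm.fractal_dimension(mask) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet(self):
        mask = sierpinski_carpet(4)  # 81 x 81
        dim = mm.fractal_dimension(mask, scales=[1, 3, 9, 27])
        assert dim == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_union_monotonicity_equal_dimension(self):
        # two 1D sets: union stays 1D
        h = np.zeros((128, 128), dtype=bool)
        h[64, :] = True
        v = np.zeros((128, 128), dtype=bool)
        v[:, 40] = True
        d_union = mm.fractal_dimension(h | v)
        assert d_union >= max(mm.fractal_dimension(h),
                              mm.fractal_dimension(v)) - 0.05

    def test_union_monotonicity_nested(self):
        blob = np.zeros((128, 128), dtype=bool)
        blob[20:80, 20:80] = True
        sub = np.zeros((128, 128), dtype=bool)
        sub[30:50, 30:50] = True
        assert mm.fractal_dimension(blob | sub) >= (
            mm.fractal_dimension(blob) - 0.05
        )

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            mm.fractal_dimension(np.zeros((64, 64), dtype=bool))


class TestMeanVelocity:
    def test_uniform_speed(self):
        maps = make_maps(velocity=np.full((32, 32), 2.0))
        assert mm.mean_velocity(maps) == pytest.approx(2.0)

    def test_two_equal_support_vessels(self):
        velocity = np.zeros((32, 32))
        density = np.zeros((32, 32))
        velocity[8, :] = 1.0
        velocity[24, :] = 3.0
        density[8, :] = density[24, :] = 1.0
        maps = make_maps(density=density, velocity=velocity)
        assert mm.mean_velocity(maps) == pytest.approx(2.0, abs=0.15)

    def test_zero_velocity_nonzero_density(self):
        maps = make_maps(density=np.ones((16, 16)),
                         velocity=np.zeros((16, 16)))
        assert mm.mean_velocity(maps) == 0.0

    def test_track_sample_averaging_option(self):
        n = 6
        tr = Track(0, np.arange(n), np.arange(n) * 36.0,
                   np.zeros(n), np.full(n, 2000.0), np.zeros(n))
        maps = make_maps(density=np.ones((8, 8)))
        assert mm.mean_velocity(maps, [tr], method="tracks") == (
            pytest.approx(2.0)
        )

    def test_empty_support_rejected(self):
        maps = make_maps(density=np.zeros((8, 8)))
        with pytest.raises(DegenerateInputError):
            mm.mean_velocity(maps)


class TestVesselDensity:
    def test_mask_equals_roi(self):
        mask = np.ones((16, 16), dtype=bool)
        assert mm.vessel_density(mask, mask) == 1.0

    def test_empty_mask(self):
        assert mm.vessel_density(np.zeros((16, 16), dtype=bool)) == 0.0

    def test_half_coverage(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:8] = True
        assert mm.vessel_density(mask) == 0.5

    def test_monotone_under_dilation(self):
        from scipy import ndimage

        rng = np.random.default_rng(2)
        mask = rng.random((32, 32)) > 0.9
        dilated = ndimage.binary_dilation(mask)
        assert mm.vessel_density(dilated) >= mm.vessel_density(mask)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            mm.vessel_density(np.ones((4, 4), dtype=bool),
                              np.zeros((4, 4), dtype=bool))


class TestMeanDiameter:
    def test_horizontal_band(self, config):
        mask = np.zeros((64, 96), dtype=bool)
        mask[20:30] = True  # 10 px tall, fine px = 4 um
        assert mm.mean_diameter(mask, config) == pytest.approx(40.0, abs=4.0)

    def test_two_disjoint_bands_mean(self, config):
        mask = np.zeros((64, 96), dtype=bool)
        mask[8:18] = True  # 10 px -> 40 um
        mask[40:60] = True  # 20 px -> 80 um
        # equal skeleton lengths: arithmetic mean of 40 and 80
        assert mm.mean_diameter(mask, config) == pytest.approx(60.0, abs=6.0)

    def test_disk_central_diameter(self, config):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        from scipy import ndimage
        from skimage.morphology import skeletonize

        skel = mm._prune_spurs(skeletonize(mask), 5)
        edt = ndimage.distance_transform_edt(mask)
        assert 2 * edt[skel].max() * 4.0 == pytest.approx(160.0, abs=8.0)

    def test_scales_linearly_with_mask_scaling(self, config):
        mask = np.zeros((64, 96), dtype=bool)
        mask[20:30] = True
        d1 = mm.mean_diameter(mask, config)
        big = np.kron(mask, np.ones((2, 2), dtype=bool))
        d2 = mm.mean_diameter(big, config)
        assert d2 == pytest.approx(2 * d1, rel=0.05)

    def test_empty_mask_rejected(self, config):
        with pytest.raises(DegenerateInputError):
            mm.mean_diameter(np.zeros((16, 16), dtype=bool), config)


class TestComputeMetrics:
    def test_bundle_fields(self, config):
        step = 2000.0 / 55.0
        tracks = []
        for i in range(8):
            n = 10
            x = 120.0 + step * np.arange(n)
            y = np.full(n, 240.0 + 4.0 * i)
            tracks.append(Track(i, np.arange(n), x, y,
                                np.full(n, step * 55.0), np.zeros(n)))
        maps = mp.build_maps(tracks, config)
        metrics = mm.compute_metrics(tracks, maps, config)
        assert metrics.tortuosity == pytest.approx(1.0, abs=0.01)
        assert metrics.mean_velocity_mm_s == pytest.approx(2.0, rel=0.05)
        assert 0.0 < metrics.vessel_density < 1.0
        assert 0.5 < metrics.fractal_dimension <= 2.0
        assert metrics.n_tracks == 8
        assert metrics.n_localizations == 80
        d = metrics.as_dict()
        assert set(d) == {
            "tortuosity", "fractal_dimension", "mean_velocity_mm_s",
            "vessel_density", "mean_diameter_um", "n_tracks",
            "n_localizations",
        }
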