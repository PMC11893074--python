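"""Tests for the synthetic scene generator and forward model."""

import numpy as np
import pytest

from ulmkit import synthetic_ceus as sc
from ulmkit.core import AcquisitionConfig


def path_chord_ratio(polyline: np.ndarray) -> float:
    arc = np.sum(np.hypot(*np.diff(polyline, axis=0).T))
    chord = np.hypot(*(polyline[-1] - polyline[0]))
    return arc / chord


FOV_UM = (2048.0, 2048.0)


class TestGenerateVesselTree:
    def test_straight_segment_ratio_is_one(self):
        segs = sc.generate_vessel_tree(1, 0.0, (20, 60), FOV_UM, seed=7)
        assert len(segs) == 1
        assert path_chord_ratio(segs[0].centerline_um) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        a = sc.generate_vessel_tree(1, 0.0, (20, 60), FOV_UM, seed=7)
        b = sc.generate_vessel_tree(1, 0.0, (20, 60), FOV_UM, seed=7)
        np.testing.assert_array_equal(a[0].centerline_um, b[0].centerline_um)
        assert a[0].diameter_um == b[0].diameter_um

    def test_tortuous_branches_exceed_ratio(self):
        segs = sc.generate_vessel_tree(3, 0.8, (20, 60), FOV_UM, seed=1)
        assert len(segs) == 3
        for seg in segs:
            assert path_chord_ratio(seg.centerline_um) > 1.05

    def test_branches_connect_to_tree(self):
        segs = sc.generate_vessel_tree(4, 0.5, (20, 60), FOV_UM, seed=3)
        for child in segs[1:]:
            start = child.centerline_um[0]
            dmin = min(
                np.min(np.hypot(*(parent.centerline_um - start).T))
                for parent in segs
                if parent is not child
            )
            # branch roots sit on (interpolated) parent polylines
            assert dmin < 25.0

    def test_invalid_branch_count(self):
        with pytest.raises(ValueError):
            sc.generate_vessel_tree(0, 0.5, (20, 60), FOV_UM, seed=0)

    def test_diameter_range_validated(self):
        with pytest.raises(ValueError):
            sc.generate_vessel_tree(1, 0.0, (20, 2000), FOV_UM, seed=0)


class TestTwoVesselPhantom:
    def test_separation_exact(self, acq_small):
        scene = sc.make_two_vessel_phantom(28.5, acq_small)
        y0 = scene.segments[0].centerline_um[0, 1]
        y1 = scene.segments[1].centerline_um[0, 1]
        assert abs(y1 - y0) == pytest.approx(28.5)
        assert abs(y1 - y0) < acq_small.pixel_size_um  # below one coarse px

    def test_far_separation_in_coarse_pixels(self, acq_small):
        scene = sc.make_two_vessel_phantom(320.0, acq_small)
        y0 = scene.segments[0].centerline_um[0, 1]
        y1 = scene.segments[1].centerline_um[0, 1]
        assert abs(y1 - y0) / acq_small.pixel_size_um == pytest.approx(10.0)

    def test_subpixel_separation_rejected(self, acq_small):
        with pytest.raises(ValueError):
            sc.make_two_vessel_phantom(2.0, acq_small)


class TestSimulateBubbles:
    def test_per_frame_displacement(self, acq_small):
        seg = sc.VesselSegment(
            np.array([[100.0, 512.0], [1400.0, 512.0]]), 0.01, 2.0
        )
        scene = sc.simulate_bubbles([seg], 0.05, acq_small, seed=2)
        # follow one track across frames: displacement = speed / frame rate
        expected = 2000.0 / 55.0
        found = 0
        for t in range(scene.n_frames - 1):
            for row in scene.bubbles[t]:
                nxt = scene.bubbles[t + 1]
                same = nxt[nxt[:, 0] == row[0]] if len(nxt) else []
                if len(same):
                    step = np.hypot(same[0][1] - row[1], same[0][2] - row[2])
                    assert step == pytest.approx(expected, rel=0.05)
                    found += 1
        assert found > 10

    def test_zero_rate_empty(self, acq_small, straight_segment):
        scene = sc.simulate_bubbles([straight_segment], 0.0, acq_small, seed=0)
        assert all(len(b) == 0 for b in scene.bubbles)

    def test_zero_speed_static(self, acq_small):
        seg = sc.VesselSegment(
            np.array([[500.0, 512.0], [900.0, 512.0]]), 20.0, 0.0
        )
        scene = sc.simulate_bubbles([seg], 0.05, acq_small, seed=4)
        for t in range(scene.n_frames - 1):
            for row in scene.bubbles[t]:
                nxt = scene.bubbles[t + 1]
                same = nxt[nxt[:, 0] == row[0]] if len(nxt) else []
                if len(same):
                    assert np.hypot(same[0][1] - row[1],
                                    same[0][2] - row[2]) == 0.0

    def test_deterministic(self, acq_small, straight_segment):
        a = sc.simulate_bubbles([straight_segment], 0.3, acq_small, seed=11)
        b = sc.simulate_bubbles([straight_segment], 0.3, acq_small, seed=11)
        for fa, fb in zip(a.bubbles, b.bubbles):
            np.testing.assert_array_equal(fa, fb)

    def test_speeds_within_lumen_tolerance(self, acq_small, straight_segment):
        scene = sc.simulate_bubbles([straight_segment], 0.2, acq_small, seed=5)
        peak = straight_segment.peak_speed_mm_s * 1000.0
        for t in range(scene.n_frames):
            for row in scene.bubbles[t]:
                speed = np.hypot(row[3], row[4])
                assert speed <= peak * 1.0001
                assert speed >= peak * 0.95 * 0.9999

    def test_positions_inside_lumen(self, acq_small, straight_segment):
        scene = sc.simulate_bubbles([straight_segment], 0.2, acq_small, seed=5)
        cy = straight_segment.centerline_um[0, 1]
        half = straight_segment.diameter_um / 2.0
        for frame in scene.bubbles:
            for row in frame:
                assert abs(row[2] - cy) <= half + 1e-9

    def test_birth_process_mean(self):
        config = AcquisitionConfig(field_of_view=(16, 32), duration_s=20.0)
        seg = sc.VesselSegment(
            np.array([[100.0, 256.0], [900.0, 256.0]]), 10.0, 2.0
        )
        rate = 0.5
        n_frames = 1000
        scene = sc.simulate_bubbles([seg], rate, config, seed=9,
                                    n_frames=n_frames)
        seen: set[int] = set()
        births = np.zeros(n_frames)
        for t, frame in enumerate(scene.bubbles):
            for row in frame:
                if int(row[0]) not in seen:
                    seen.add(int(row[0]))
                    births[t] += 1
        # Poisson mean within 3 standard errors
        se = np.sqrt(rate / n_frames)
        assert abs(births.mean() - rate) < 3 * se


class TestRenderFrames:
    def test_single_static_bubble_argmax(self, acq_small):
        seg = sc.VesselSegment(
            np.array([[700.0, 500.0], [900.0, 500.0]]), 0.01, 0.0
        )
        scene = sc.VascScene(
            [seg], [np.array([[0, 740.0, 500.0, 0.0, 0.0]])], None,
            acq_small, seed=1,
        )
        _, ceus = sc.render_frames(scene, noise={"background_level": 0.0})
        r, c = np.unravel_index(np.argmax(ceus.frames[0]),
                                ceus.frames[0].shape)
        px = acq_small.pixel_size_um
        assert int(740.0 / px) == c
        assert int(500.0 / px) == r

    def test_no_bubbles_no_noise_zero(self, acq_small, straight_segment):
        scene = sc.simulate_bubbles([straight_segment], 0.0, acq_small, seed=0)
        _, ceus = sc.render_frames(scene, noise={"background_level": 0.0})
        assert np.all(ceus.frames == 0)

    def test_bit_identical_rerender(self, sparse_scene):
        b1, c1 = sc.render_frames(sparse_scene)
        b2, c2 = sc.render_frames(sparse_scene)
        np.testing.assert_array_equal(c1.frames, c2.frames)
        np.testing.assert_array_equal(b1.frames, b2.frames)

    def test_blob_mass_linear_in_amplitude(self, acq_small):
        seg = sc.VesselSegment(
            np.array([[700.0, 500.0], [900.0, 500.0]]), 0.01, 0.0
        )
        scene = sc.VascScene(
            [seg], [np.array([[0, 740.0, 500.0, 0.0, 0.0]])], None,
            acq_small, seed=1,
        )
        masses = []
        for amp in (0.5, 1.0):
            _, ceus = sc.render_frames(
                scene,
                noise={"background_level": 0.0,
                       "bubble_amplitude_range": (amp, amp)},
            )
            masses.append(ceus.frames[0].sum())
        assert masses[1] == pytest.approx(2 * masses[0], rel=1e-9)


class TestApplyTissueMotion:
    def test_zero_amplitudes_identity(self, sparse_scene):
        moved = sc.apply_tissue_motion(sparse_scene)
        assert np.all(moved.motion_fields == 0)

    def test_quarter_period_translation(self, straight_segment):
        # 40 Hz so that t = 0.25 s lands exactly on frame 10
        config = AcquisitionConfig(field_of_view=(16, 24), duration_s=1.0,
                                   frame_rate_hz=40.0)
        scene = sc.simulate_bubbles([straight_segment], 0.0, config, seed=0)
        moved = sc.apply_tissue_motion(scene, translation_amplitude_um=64.0,
                                       period_s=1.0)
        field = moved.motion_fields[10]
        np.testing.assert_allclose(field[..., 0], 64.0, rtol=1e-9)
        np.testing.assert_allclose(field[..., 1], 0.0, atol=1e-9)

    def test_nonrigid_amplitude_bound(self, sparse_scene):
        moved = sc.apply_tissue_motion(sparse_scene,
                                       nonrigid_amplitude_um=10.0)
        for t in range(moved.n_frames):
            f = moved.motion_fields[t]
            for ch in range(2):
                dev = np.abs(f[..., ch] - f[..., ch].mean())
                assert dev.max() <= 10.0 + 1e-9

    def test_negative_amplitude_rejected(self, sparse_scene):
        with pytest.raises(ValueError):
            sc.apply_tissue_motion(sparse_scene,
                                   translation_amplitude_um=-1.0)


class TestProfileHelpers:
    def test_two_peaks_detected(self):
        x = np.arange(60, dtype=float)
        prof = np.exp(-((x - 25) ** 2) / 8) + np.exp(-((x - 35) ** 2) / 8)
        assert sc.profile_has_two_peaks(prof)

    def test_single_peak_rejected(self):
        x = np.arange(60, dtype=float)
        prof = np.exp(-((x - 30) ** 2) / 50)
        assert not sc.profile_has_two_peaks(prof)

    def test_shallow_dip_rejected(self):
        x = np.arange(60, dtype=float)
        prof = np.exp(-((x - 28) ** 2) / 60) + np.exp(-((x - 32) ** 2) / 60)
        assert not sc.profile_has_two_peaks(prof)


class TestSceneIO:
    def test_save_and_reload_truth(self, tmp_path, sparse_scene,
                                   sparse_rendered):
        import json

        bmode, ceus = sparse_rendered
        sc.save_scene(sparse_scene, tmp_path)
        sc.save_frames(ceus, tmp_path / "ceus.tif")
        arr = np.loadtxt(tmp_path / "bubbles.csv", delimiter=",", skiprows=1)
        assert arr.shape[1] == 6
        assert len(arr) == sum(len(b) for b in sparse_scene.bubbles)
        desc = json.loads((tmp_path / "scene.json").read_text())
        assert desc["seed"] == sparse_scene.seed
        import tifffile

        frames = tifffile.imread(tmp_path / "ceus.tif")
        assert frames.shape == ceus.frames.shape
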