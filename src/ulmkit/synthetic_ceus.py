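"""Synthetic contrast-enhanced ultrasound (CEUS) scenes with ground truth.

Generates vessel geometries, stochastic microbubble transits along them,
slow periodic tissue motion, and renders paired B-mode / CEUS frame
sequences on the coarse acquisition grid.  Everything is deterministic
given a seed, and the ground truth (bubble positions/velocities, motion
fields, vessel centrelines) is retained for oracle comparisons.

Forward model notes: microbubbles are rendered as isotropic 2D Gaussian
blobs (the system PSF); B-mode tissue is a static multiplicative-speckle
texture warped by the scene's motion field.  Flow uses a blunted
("plug-like") lateral speed profile so that bubbles fill the lumen while
per-bubble speeds stay within 5% of the segment's peak speed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from ulmkit.core import AcquisitionConfig, FrameSequence, pixel_centers_um

__all__ = [
    "VesselSegment",
    "VascScene",
    "generate_vessel_tree",
    "make_two_vessel_phantom",
    "simulate_bubbles",
    "simulate_regular_transits",
    "apply_tissue_motion",
    "render_frames",
    "cross_profile",
    "profile_has_two_peaks",
    "bubbles_to_array",
    "save_scene",
    "save_frames",
]

#: fraction of the lumen radius that bubble centres may occupy
LUMEN_MARGIN = 1.0
#: lateral speed profile: speed = peak * (1 - PROFILE_FLATNESS * f^2),
#: f in [-1, 1] across the lumen.  Kept small so all speeds are within
#: 5% of peak while positions remain uniform across the lumen.
PROFILE_FLATNESS = 0.05


@dataclass(frozen=True)
class VesselSegment:
    """One vessel branch: a polyline centreline with diameter and speed."""

    centerline_um: np.ndarray  # (N, 2) points (x, y) in um
    diameter_um: float
    peak_speed_mm_s: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline_um, dtype=float)
        object.__setattr__(self, "centerline_um", pts)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("centerline must be an (N>=2, 2) array")
        if np.allclose(pts[0], pts[-1]) and pts.shape[0] == 2:
            raise ValueError("centerline needs >=2 distinct points")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if self.peak_speed_mm_s < 0:
            raise ValueError("peak_speed_mm_s must be nonnegative")

    @property
    def arc_lengths_um(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.centerline_um, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length_um(self) -> float:
        return float(self.arc_lengths_um[-1])

    def point_at(self, s_um: float) -> np.ndarray:
        """Centreline point at arc length ``s_um`` (clamped)."""
        s = np.clip(s_um, 0.0, self.length_um)
        arcs = self.arc_lengths_um
        x = np.interp(s, arcs, self.centerline_um[:, 0])
        y = np.interp(s, arcs, self.centerline_um[:, 1])
        return np.array([x, y])

    def tangent_at(self, s_um: float) -> np.ndarray:
        """Unit tangent at arc length ``s_um``."""
        arcs = self.arc_lengths_um
        i = int(np.clip(np.searchsorted(arcs, s_um, side="right") - 1, 0,
                        len(arcs) - 2))
        d = self.centerline_um[i + 1] - self.centerline_um[i]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0])

    def normal_at(self, s_um: float) -> np.ndarray:
        t = self.tangent_at(s_um)
        return np.array([-t[1], t[0]])


@dataclass
class VascScene:
    """Ground-truth scene: vessels, per-frame bubbles, motion fields."""

    segments: list[VesselSegment]
    bubbles: list[np.ndarray]  # per frame, (n, 5): id, x, y, vx, vy
    motion_fields: np.ndarray | None  # (T, H, W, 2) um, last axis (dx, dy)
    config: AcquisitionConfig
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.bubbles)

    def motion_at(self, frame: int, positions_um: np.ndarray) -> np.ndarray:
        """Interpolate the frame's motion field at (x, y) positions (um)."""
        positions_um = np.atleast_2d(positions_um)
        if self.motion_fields is None:
            return np.zeros_like(positions_um)
        field = self.motion_fields[frame]
        px = self.config.pixel_size_um
        rows = positions_um[:, 1] / px - 0.5
        cols = positions_um[:, 0] / px - 0.5
        dx = ndimage.map_coordinates(field[..., 0], [rows, cols], order=1,
                                     mode="nearest")
        dy = ndimage.map_coordinates(field[..., 1], [rows, cols], order=1,
                                     mode="nearest")
        return np.column_stack([dx, dy])


def _random_walk_branch(
    rng: np.random.Generator,
    start_um: np.ndarray,
    heading_rad: float,
    tortuosity_level: float,
    fov_um: tuple[float, float],
    step_um: float,
    margin_um: float,
) -> np.ndarray:
    """Smooth heading-random-walk polyline, stopped at the field margin."""
    h_um, w_um = fov_um
    max_steps = int(2.0 * max(h_um, w_um) / step_um)
    pts = [np.asarray(start_um, dtype=float)]
    theta = heading_rad
    for _ in range(max_steps):
        theta += tortuosity_level * 0.30 * rng.standard_normal()
        nxt = pts[-1] + step_um * np.array([np.cos(theta), np.sin(theta)])
        if not (margin_um <= nxt[0] <= w_um - margin_um
                and margin_um <= nxt[1] <= h_um - margin_um):
            break
        pts.append(nxt)
    if len(pts) < 2:  # degenerate start near the margin: force a short stub
        pts.append(pts[-1] + step_um * np.array([np.cos(theta),
                                                 np.sin(theta)]))
    return np.array(pts)


def generate_vessel_tree(
    n_branches: int,
    tortuosity_level: float,
    diameter_range_um: tuple[float, float],
    fov_um: tuple[float, float],
    seed: int,
    step_um: float = 20.0,
    speed_range_mm_s: tuple[float, float] = (1.0, 3.0),
) -> list[VesselSegment]:
    """Connected branching centrelines as smooth random walks.

    ``tortuosity_level`` = 0 yields straight segments; larger values add
    heading diffusion.  Branches after the first start on a previously
    generated segment, so the tree is connected.  Deterministic for a
    given ``seed``.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    h_um, w_um = fov_um
    if h_um <= 0 or w_um <= 0:
        raise ValueError("fov must be positive")
    lo, hi = diameter_range_um
    if not (0 < lo <= hi < min(fov_um) / 4):
        raise ValueError("diameter_range_um must lie within (0, fov/4)")

    rng = np.random.default_rng(seed)
    margin = max(2 * step_um, 0.05 * min(fov_um))
    segments: list[VesselSegment] = []
    for b in range(n_branches):
        if b == 0:
            start = np.array([
                margin + step_um,
                rng.uniform(0.3 * h_um, 0.7 * h_um),
            ])
            heading = rng.uniform(-np.pi / 6, np.pi / 6)
        else:
            parent = segments[rng.integers(len(segments))]
            arcs = parent.arc_lengths_um
            s0 = rng.uniform(0.2, 0.8) * arcs[-1]
            start = parent.point_at(s0)
            t = parent.tangent_at(s0)
            heading = np.arctan2(t[1], t[0]) + rng.choice([-1, 1]) * rng.uniform(
                np.pi / 9, np.pi / 3
            )
        centerline = _random_walk_branch(
            rng, start, heading, tortuosity_level, fov_um, step_um, margin
        )
        segments.append(
            VesselSegment(
                centerline_um=centerline,
                diameter_um=float(rng.uniform(lo, hi)),
                peak_speed_mm_s=float(rng.uniform(*speed_range_mm_s)),
            )
        )
    return segments


def make_two_vessel_phantom(
    separation_um: float,
    config: AcquisitionConfig,
    speed_mm_s: float = 2.0,
    diameter_um: float = 8.0,
    rate_per_frame: float = 0.03,
    seed: int = 0,
) -> VascScene:
    """Resolution phantom: two straight parallel vessels.

    Centrelines are horizontal, exactly ``separation_um`` apart
    (centre-to-centre), centred in the field of view, each carrying
    stochastic bubble transits at a fixed speed.  Flow directions are
    opposite, and the default bubble rate is kept low, so that
    overlapping-PSF interactions between the two vessels stay brief:
    sparse transits are what make super-resolution separation possible.
    """
    if separation_um <= 0:
        raise ValueError("separation_um must be positive")
    if separation_um < config.fine_pixel_um:
        raise ValueError(
            f"separation_um={separation_um} below one fine pixel "
            f"({config.fine_pixel_um} um)"
        )
    h_um, w_um = config.extent_um
    cy = h_um / 2.0
    x0, x1 = 0.08 * w_um, 0.92 * w_um
    segments = [
        VesselSegment(
            centerline_um=np.array([[x0, cy - separation_um / 2],
                                    [x1, cy - separation_um / 2]]),
            diameter_um=diameter_um,
            peak_speed_mm_s=speed_mm_s,
        ),
        VesselSegment(  # reversed centreline: counter-flow
            centerline_um=np.array([[x1, cy + separation_um / 2],
                                    [x0, cy + separation_um / 2]]),
            diameter_um=diameter_um,
            peak_speed_mm_s=speed_mm_s,
        ),
    ]
    return simulate_bubbles(segments, rate_per_frame, config, seed)


def simulate_bubbles(
    segments: list[VesselSegment],
    rate_per_frame: float,
    config: AcquisitionConfig,
    seed: int,
    n_frames: int | None = None,
) -> VascScene:
    """Advect stochastically appearing bubbles along vessel centrelines.

    Bubbles are born at segment inlets as a per-frame Poisson process with
    mean ``rate_per_frame`` per segment, drift at the segment's speed
    (blunted lateral profile), keep a fixed lateral offset inside the
    lumen, and exit at the segment end.  Per-frame ground-truth velocity
    equals displacement times frame rate.
    """
    if rate_per_frame < 0:
        raise ValueError("rate_per_frame must be >= 0")
    T = n_frames if n_frames is not None else config.n_frames
    dt = config.dt_s
    rng = np.random.default_rng(seed)

    per_frame: list[list[np.ndarray]] = [[] for _ in range(T)]
    next_id = 0
    for seg in segments:
        births = rng.poisson(rate_per_frame, size=T)
        for t0 in range(T):
            for _ in range(births[t0]):
                f = rng.uniform(-1.0, 1.0)  # lateral offset fraction
                offset = f * LUMEN_MARGIN * seg.diameter_um / 2.0
                speed = (seg.peak_speed_mm_s * 1000.0
                         * (1.0 - PROFILE_FLATNESS * f * f))  # um/s
                s = rng.uniform(0.0, max(speed * dt, 1e-9))
                positions = []
                # advance until the bubble exits the segment or the clip ends;
                # speed 0 keeps the bubble static until the last frame
                while s <= seg.length_um and t0 + len(positions) < T:
                    positions.append(seg.point_at(s) + offset * seg.normal_at(s))
                    s += speed * dt
                if not positions:
                    continue
                pos = np.array(positions)
                if len(pos) >= 2:
                    v = np.diff(pos, axis=0) / dt
                    v = np.vstack([v, v[-1]])
                else:
                    v = (speed * seg.tangent_at(0.0))[None, :]
                for k in range(len(pos)):
                    per_frame[t0 + k].append(
                        np.array([next_id, pos[k, 0], pos[k, 1],
                                  v[k, 0], v[k, 1]])
                    )
                next_id += 1

    bubbles = [
        np.array(rows) if rows else np.empty((0, 5)) for rows in per_frame
    ]
    return VascScene(
        segments=list(segments),
        bubbles=bubbles,
        motion_fields=None,
        config=config,
        seed=seed,
    )


def simulate_regular_transits(
    segments: list[VesselSegment],
    spacing_frames: int,
    config: AcquisitionConfig,
    seed: int,
    n_frames: int | None = None,
) -> VascScene:
    """Deterministically spaced bubble transits (one birth per
    ``spacing_frames`` per segment).

    Useful for oracle experiments where stochastic birth clustering would
    confound the measurement (e.g. motion-correction scoring): births are
    periodic, so concurrent bubbles in one vessel keep a fixed, large
    along-vessel separation.  Lateral lumen offsets still come from the
    seeded generator.
    """
    if spacing_frames < 1:
        raise ValueError("spacing_frames must be >= 1")
    T = n_frames if n_frames is not None else config.n_frames
    dt = config.dt_s
    rng = np.random.default_rng(seed)
    per_frame: list[list[np.ndarray]] = [[] for _ in range(T)]
    next_id = 0
    for seg in segments:
        for t0 in range(0, T, spacing_frames):
            f = rng.uniform(-1.0, 1.0)
            offset = f * LUMEN_MARGIN * seg.diameter_um / 2.0
            speed = (seg.peak_speed_mm_s * 1000.0
                     * (1.0 - PROFILE_FLATNESS * f * f))
            s = 0.0
            positions = []
            while s <= seg.length_um and t0 + len(positions) < T:
                positions.append(seg.point_at(s) + offset * seg.normal_at(s))
                s += speed * dt
                if speed <= 0:
                    break
            if not positions:
                continue
            pos = np.array(positions)
            if len(pos) >= 2:
                v = np.diff(pos, axis=0) / dt
                v = np.vstack([v, v[-1]])
            else:
                v = (speed * seg.tangent_at(0.0))[None, :]
            for k in range(len(pos)):
                per_frame[t0 + k].append(
                    np.array([next_id, pos[k, 0], pos[k, 1], v[k, 0],
                              v[k, 1]])
                )
            next_id += 1
    bubbles = [
        np.array(rows) if rows else np.empty((0, 5)) for rows in per_frame
    ]
    return VascScene(segments=list(segments), bubbles=bubbles,
                     motion_fields=None, config=config, seed=seed)


def apply_tissue_motion(
    scene: VascScene,
    translation_amplitude_um: float = 0.0,
    period_s: float = 1.0,
    nonrigid_amplitude_um: float = 0.0,
    nonrigid_period_s: float | None = None,
    direction: tuple[float, float] = (1.0, 0.0),
) -> VascScene:
    """Attach per-frame displacement fields to a scene.

    The field is a global sinusoidal translation (along ``direction``)
    plus a smooth zero-mean nonrigid component bounded by
    ``nonrigid_amplitude_um``.  True fields are retained on the returned
    scene so estimators can be scored against them.
    """
    if translation_amplitude_um < 0 or nonrigid_amplitude_um < 0:
        raise ValueError("amplitudes must be >= 0")
    cfg = scene.config
    H, W = cfg.field_of_view
    T = scene.n_frames
    t = np.arange(T) * cfg.dt_s
    d = np.asarray(direction, dtype=float)
    d /= max(np.linalg.norm(d), 1e-12)

    fields = np.zeros((T, H, W, 2))
    trans = translation_amplitude_um * np.sin(2 * np.pi * t / period_s)
    fields[..., 0] += trans[:, None, None] * d[0]
    fields[..., 1] += trans[:, None, None] * d[1]

    if nonrigid_amplitude_um > 0:
        xs = pixel_centers_um(W, cfg.pixel_size_um)
        ys = pixel_centers_um(H, cfg.pixel_size_um)
        h_um, w_um = cfg.extent_um
        gx = np.sin(2 * np.pi * xs / w_um)[None, :] * np.sin(
            2 * np.pi * ys / h_um
        )[:, None]
        gx -= gx.mean()
        gx /= max(np.abs(gx).max(), 1e-12)
        gy = np.cos(2 * np.pi * xs / w_um)[None, :] * np.sin(
            2 * np.pi * ys / h_um
        )[:, None]
        gy -= gy.mean()
        gy /= max(np.abs(gy).max(), 1e-12)
        p2 = nonrigid_period_s if nonrigid_period_s is not None else 2 * period_s
        amp = nonrigid_amplitude_um * np.sin(2 * np.pi * t / p2)
        fields[..., 0] += amp[:, None, None] * gx[None]
        fields[..., 1] += amp[:, None, None] * gy[None]

    return dataclasses.replace(scene, motion_fields=fields)


def _bubble_amplitude(scene_seed: int, track_id: int,
                      amp_range: tuple[float, float]) -> float:
    rng = np.random.default_rng([scene_seed, 104729, int(track_id)])
    return float(rng.uniform(*amp_range))


def render_frames(
    scene: VascScene,
    psf_sigma_um: float = 100.0,
    noise: dict | None = None,
) -> tuple[FrameSequence, FrameSequence]:
    """Render (B-mode, CEUS) frame stacks on the coarse grid.

    CEUS frames are sums of isotropic Gaussian blobs at the motion-shifted
    bubble positions plus a background noise floor; B-mode frames are a
    fixed Rayleigh-speckle texture warped by the scene's motion field.
    Bit-identical for identical scenes.
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be positive")
    noise = dict(noise or {})
    background_level = float(noise.get("background_level", 0.01))
    speckle_contrast = float(noise.get("speckle_contrast", 0.5))
    amp_range = tuple(noise.get("bubble_amplitude_range", (0.6, 1.0)))

    cfg = scene.config
    H, W = cfg.field_of_view
    px = cfg.pixel_size_um
    T = scene.n_frames
    rng = np.random.default_rng([scene.seed, 977])

    # static tissue texture (mean ~ 1) with enough gradient for registration
    speckle = rng.rayleigh(scale=1.0, size=(H, W))
    texture = ndimage.gaussian_filter(speckle, 1.0)
    texture = 1.0 + speckle_contrast * (texture - texture.mean()) / max(
        texture.std(), 1e-12
    )
    texture = np.clip(texture, 0.0, None)

    xs = pixel_centers_um(W, px)
    ys = pixel_centers_um(H, px)
    win = int(np.ceil(4 * psf_sigma_um / px))

    ceus = np.zeros((T, H, W))
    bmode = np.zeros((T, H, W))
    rows_idx, cols_idx = np.mgrid[0:H, 0:W].astype(float)
    for t in range(T):
        frame = ceus[t]
        bubbles = scene.bubbles[t]
        if len(bubbles):
            shifts = scene.motion_at(t, bubbles[:, 1:3])
            for b, shift in zip(bubbles, shifts):
                tid, x, y = int(b[0]), b[1] + shift[0], b[2] + shift[1]
                amp = _bubble_amplitude(scene.seed, tid, amp_range)
                ci = int(round(x / px - 0.5))
                ri = int(round(y / px - 0.5))
                r0, r1 = max(ri - win, 0), min(ri + win + 1, H)
                c0, c1 = max(ci - win, 0), min(ci + win + 1, W)
                if r0 >= r1 or c0 >= c1:
                    continue
                gx = np.exp(-((xs[c0:c1] - x) ** 2) / (2 * psf_sigma_um**2))
                gy = np.exp(-((ys[r0:r1] - y) ** 2) / (2 * psf_sigma_um**2))
                frame[r0:r1, c0:c1] += amp * gy[:, None] * gx[None, :]
        if background_level > 0:
            frame += background_level * rng.rayleigh(scale=1.0, size=(H, W))

        if scene.motion_fields is not None:
            f = scene.motion_fields[t]
            bmode[t] = ndimage.map_coordinates(
                texture,
                [rows_idx - f[..., 1] / px, cols_idx - f[..., 0] / px],
                order=1,
                mode="nearest",
            )
        else:
            bmode[t] = texture

    return (
        FrameSequence(bmode, px, cfg.frame_rate_hz, channel="bmode"),
        FrameSequence(ceus, px, cfg.frame_rate_hz, channel="ceus"),
    )


def cross_profile(map2d: np.ndarray,
                  x_fraction_range: tuple[float, float] = (0.25, 0.75)
                  ) -> np.ndarray:
    """Intensity profile perpendicular to horizontal phantom vessels.

    Averages the map over a central band of columns, returning a 1D
    profile along the row (y) axis.
    """
    map2d = np.asarray(map2d, dtype=float)
    W = map2d.shape[1]
    c0 = int(x_fraction_range[0] * W)
    c1 = max(int(x_fraction_range[1] * W), c0 + 1)
    return map2d[:, c0:c1].mean(axis=1)


def profile_has_two_peaks(profile: np.ndarray, dip_ratio: float = 0.8,
                          min_separation: int = 2) -> bool:
    """Two distinct local maxima with an inter-peak dip?

    True when the two strongest local maxima are at least
    ``min_separation`` samples apart and the minimum between them is
    below ``dip_ratio`` times the lower peak — the operational
    two-vessel resolution criterion.
    """
    profile = np.asarray(profile, dtype=float)
    maxima = [
        i for i in range(1, len(profile) - 1)
        if profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
        and profile[i] > 0
    ]
    if len(maxima) < 2:
        return False
    by_height = sorted(maxima, key=lambda i: profile[i], reverse=True)
    p1 = by_height[0]
    p2 = next((i for i in by_height[1:] if abs(i - p1) >= min_separation),
              None)
    if p2 is None:
        return False
    lo, hi = sorted((p1, p2))
    dip = profile[lo:hi + 1].min()
    return bool(dip < dip_ratio * min(profile[p1], profile[p2]))


def bubbles_to_array(scene: VascScene) -> np.ndarray:
    """Flatten ground truth to (n, 6): frame, track_id, x, y, vx, vy."""
    rows = []
    for t, frame_bubbles in enumerate(scene.bubbles):
        for b in frame_bubbles:
            rows.append([t, b[0], b[1], b[2], b[3], b[4]])
    return np.array(rows) if rows else np.empty((0, 6))


def save_frames(seq: FrameSequence, path: str | Path) -> None:
    """Write a frame stack as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), seq.frames.astype(np.float32),
                     photometric="minisblack")


def save_scene(scene: VascScene, out_dir: str | Path) -> None:
    """Write ground truth: bubbles CSV plus a JSON scene descriptor."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = bubbles_to_array(scene)
    header = "frame,track_id,x_um,y_um,vx_um_s,vy_um_s"
    np.savetxt(out / "bubbles.csv", arr, delimiter=",", header=header,
               comments="", fmt="%.6g")
    descriptor = {
        "seed": scene.seed,
        "config": dataclasses.asdict(scene.config),
        "n_frames": scene.n_frames,
        "segments": [
            {
                "centerline_um": seg.centerline_um.tolist(),
                "diameter_um": seg.diameter_um,
                "peak_speed_mm_s": seg.peak_speed_mm_s,
            }
            for seg in scene.segments
        ],
    }
    (out / "scene.json").write_text(json.dumps(descriptor, indent=2))
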