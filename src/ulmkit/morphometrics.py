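"""Vascular morphometrics from tracks and super-resolved maps.

Five per-acquisition readouts: trajectory tortuosity (arc length over
chord), box-counting fractal dimension of the binarized density map,
mean velocity over the vessel support, vessel density (covered fraction
of the region of interest), and mean vessel diameter (twice the distance
from skeleton pixels to the nearest boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from ulmkit.core import AcquisitionConfig, DegenerateInputError, Track
from ulmkit.mapping import ULMMaps

__all__ = [
    "VascMetrics",
    "tortuosity",
    "mean_tortuosity",
    "fractal_dimension",
    "mean_velocity",
    "vessel_density",
    "mean_diameter",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

#: minimum endpoint separation (um) for a tortuosity to be defined
TORTUOSITY_MIN_CHORD_UM = 8.0


def tortuosity(track: Track | np.ndarray,
               min_chord_um: float = TORTUOSITY_MIN_CHORD_UM) -> float:
    """Arc length of a trajectory divided by its endpoint distance.

    Accepts a :class:`Track` or an (N, 2) polyline in um.  Near-closed
    trajectories (chord below ``min_chord_um``) are rejected with a
    ``ValueError`` so callers can exclude and log them.
    """
    pts = track.points if isinstance(track, Track) else np.asarray(track,
                                                                   float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("trajectory needs at least 2 points")
    chord = float(np.hypot(*(pts[-1] - pts[0])))
    if chord <= min_chord_um:
        raise ValueError(
            f"endpoint distance {chord:.3g} um <= {min_chord_um} um"
        )
    arc = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    return arc / chord


def mean_tortuosity(tracks: list[Track],
                    min_chord_um: float = TORTUOSITY_MIN_CHORD_UM
                    ) -> tuple[float, np.ndarray]:
    """Acquisition-level tortuosity: mean over retained tracks.

    Returns ``(mean, per_track_values)``; near-closed trajectories are
    excluded and logged.
    """
    values = []
    excluded = 0
    for tr in tracks:
        try:
            values.append(tortuosity(tr, min_chord_um))
        except ValueError:
            excluded += 1
    if excluded:
        logger.info("tortuosity: excluded %d near-closed trajectories",
                    excluded)
    if not values:
        raise DegenerateInputError("no track with usable endpoints")
    arr = np.array(values)
    return float(arr.mean()), arr


def _box_count(mask: np.ndarray, size: int) -> int:
    """Number of size x size boxes containing at least one set pixel."""
    H, W = mask.shape
    ph = (-H) % size
    pw = (-W) % size
    padded = np.pad(mask, ((0, ph), (0, pw)))
    view = padded.reshape(padded.shape[0] // size, size,
                          padded.shape[1] // size, size)
    return int(view.any(axis=(1, 3)).sum())


def fractal_dimension(mask: np.ndarray,
                      scales: list[int] | None = None) -> float:
    """Box-counting dimension of a binary mask.

    Counts occupied boxes over a dyadic scale ladder (1, 2, 4, ... up to
    ``min(H, W)/4`` by default) and returns the slope of the
    least-squares fit of ``log N(s)`` against ``log(1/s)``.  Scales where
    fewer than 4 boxes are occupied are dropped when at least 3 scales
    remain (fit-stability rule).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateInputError("empty mask has no fractal dimension")
    if scales is None:
        max_scale = max(min(mask.shape) // 4, 2)
        scales = []
        s = 1
        while s <= max_scale:
            scales.append(s)
            s *= 2
    counts = np.array([_box_count(mask, s) for s in scales], dtype=float)
    scales_arr = np.array(scales, dtype=float)

    keep = np.ones(len(scales_arr), dtype=bool)
    sparse = counts < 4
    if sparse.any() and (~sparse).sum() >= 3:
        keep = ~sparse
    if keep.sum() < 2:
        keep = np.ones(len(scales_arr), dtype=bool)

    slope, _ = np.polyfit(np.log(1.0 / scales_arr[keep]),
                          np.log(counts[keep]), 1)
    return float(slope)


def mean_velocity(maps: ULMMaps, tracks: list[Track] | None = None,
                  method: str = "map") -> float:
    """Mean speed in mm/s.

    ``method="map"`` (default) averages the velocity map over the vessel
    support (pixels with positive density); ``method="tracks"`` averages
    per-step speeds over all track samples instead.
    """
    if method == "tracks":
        if not tracks:
            raise DegenerateInputError("no tracks supplied")
        speeds = np.concatenate([
            tr.speeds_um_s[: max(len(tr) - 1, 1)] for tr in tracks
        ])
        return float(speeds.mean()) / 1000.0
    support = maps.density > 0
    if not support.any():
        raise DegenerateInputError("velocity map has empty support")
    return float(maps.velocity_mm_s[support].mean())


def vessel_density(mask: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Fraction of the region of interest covered by the vessel mask."""
    mask = np.asarray(mask).astype(bool)
    if roi is None:
        roi = np.ones_like(mask, dtype=bool)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != mask.shape:
        raise ValueError("roi and mask must share a shape")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("roi must be nonempty")
    return float(np.logical_and(mask, roi).sum() / n_roi)


def _prune_spurs(skeleton: np.ndarray, n_iter: int) -> np.ndarray:
    """Remove up to ``n_iter`` layers of skeleton endpoints (spur pruning).

    If pruning would erase the skeleton entirely, the unpruned skeleton
    is kept (tiny blobs collapse to near-point skeletons).
    """
    kernel = np.ones((3, 3))
    pruned = skeleton.copy()
    for _ in range(n_iter):
        neighbours = ndimage.convolve(pruned.astype(int), kernel,
                                      mode="constant") - pruned
        endpoints = pruned & (neighbours <= 1)
        nxt = pruned & ~endpoints
        if not nxt.any():
            return skeleton
        pruned = nxt
    return pruned


def mean_diameter(
    mask: np.ndarray,
    config: AcquisitionConfig,
    prune_px: int = 5,
) -> float:
    """Mean vessel diameter (um) via skeleton + distance transform.

    The mask is thinned to 1-px centrelines (spurs shorter than
    ``prune_px`` removed); at each skeleton pixel the diameter is twice
    the Euclidean distance to the nearest background pixel, and the mean
    over skeleton pixels is converted to um with the fine pitch.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    skeleton = skeletonize(mask)
    if not skeleton.any():
        raise DegenerateInputError("mask produced an empty skeleton")
    skeleton = _prune_spurs(skeleton, prune_px)
    edt = ndimage.distance_transform_edt(mask)
    diameters_px = 2.0 * edt[skeleton]
    return float(diameters_px.mean()) * config.fine_pixel_um


@dataclass
class VascMetrics:
    """Per-acquisition vascular readouts."""

    tortuosity: float
    fractal_dimension: float
    mean_velocity_mm_s: float
    vessel_density: float
    mean_diameter_um: float
    n_tracks: int
    n_localizations: int

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    tracks: list[Track],
    maps: ULMMaps,
    config: AcquisitionConfig,
    roi: np.ndarray | None = None,
    velocity_method: str = "map",
) -> VascMetrics:
    """All five readouts from one acquisition's tracks and maps."""
    tort_mean, _ = mean_tortuosity(tracks)
    return VascMetrics(
        tortuosity=tort_mean,
        fractal_dimension=fractal_dimension(maps.mask),
        mean_velocity_mm_s=mean_velocity(maps, tracks, velocity_method),
        vessel_density=vessel_density(maps.mask, roi),
        mean_diameter_um=mean_diameter(maps.mask, config),
        n_tracks=len(tracks),
        n_localizations=int(sum(len(t) for t in tracks)),
    )
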