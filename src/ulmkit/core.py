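"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* Image arrays are indexed ``[row, col]`` (= ``[y, x]``); frame stacks are
  ``(T, H, W)``.
* Physical positions are ``(x_um, y_um)`` with ``x`` along columns
  (lateral) and ``y`` along rows (axial), in micrometres.
* The centre of pixel ``(row, col)`` is at
  ``x = (col + 0.5) * pixel_size_um``, ``y = (row + 0.5) * pixel_size_um``.
* Velocities are in um/s unless a name says ``mm_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of one acquisition.

    ``pixel_size_um`` is the coarse acquisition grid; ``fine_pixel_um`` the
    reconstruction grid.  The coarse pitch must be an integer multiple of
    the fine pitch.
    """

    pixel_size_um: float = 32.0
    fine_pixel_um: float = 4.0
    frame_rate_hz: float = 55.0
    duration_s: float = 20.0
    field_of_view: tuple[int, int] = (64, 64)  # (height_px, width_px), coarse
    center_frequency_mhz: float = 15.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.fine_pixel_um <= 0:
            raise ValueError("pixel sizes must be positive")
        ratio = self.pixel_size_um / self.fine_pixel_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "pixel_size_um must be an integer multiple of fine_pixel_um "
                f"(got ratio {ratio})"
            )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.duration_s * self.frame_rate_hz < 3:
            raise ValueError("acquisition must span at least 3 frames")
        h, w = self.field_of_view
        if h < 1 or w < 1:
            raise ValueError("field_of_view must be positive")

    @property
    def upsample_factor(self) -> int:
        """Integer ratio coarse pitch / fine pitch."""
        return int(round(self.pixel_size_um / self.fine_pixel_um))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height_um, width_um) of the field of view."""
        h, w = self.field_of_view
        return (h * self.pixel_size_um, w * self.pixel_size_um)

    @property
    def fine_shape(self) -> tuple[int, int]:
        h, w = self.field_of_view
        f = self.upsample_factor
        return (h * f, w * f)


@dataclass
class FrameSequence:
    """A time-ordered stack of 2D intensity frames for one channel."""

    frames: np.ndarray  # (T, H, W), nonnegative
    pixel_size_um: float
    frame_rate_hz: float
    channel: str = "ceus"  # {"bmode", "ceus"}

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.channel not in ("bmode", "ceus"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def max_intensity_projection(self) -> np.ndarray:
        return self.frames.max(axis=0)


@dataclass(frozen=True)
class Localization:
    """One detected microbubble on the fine grid."""

    frame: int
    x_um: float
    y_um: float
    score: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um])


@dataclass
class Track:
    """An ordered chain of localizations with per-step velocities.

    Frame indices increase strictly by 1.  ``vx_um_s``/``vy_um_s`` hold the
    forward-difference velocity (displacement x frame rate); the last
    sample repeats the previous step so the arrays stay aligned.
    """

    track_id: int
    frames: np.ndarray  # (N,) int
    x_um: np.ndarray  # (N,)
    y_um: np.ndarray  # (N,)
    vx_um_s: np.ndarray  # (N,)
    vy_um_s: np.ndarray  # (N,)
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("x_um", "y_um", "vx_um_s", "vy_um_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.scores is None:
            self.scores = np.full(self.frames.shape, np.nan)
        n = len(self.frames)
        if any(
            len(getattr(self, a)) != n
            for a in ("x_um", "y_um", "vx_um_s", "vy_um_s", "scores")
        ):
            raise ValueError("track arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frame indices must increase by exactly 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in um."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def speeds_um_s(self) -> np.ndarray:
        return np.hypot(self.vx_um_s, self.vy_um_s)

    def mean_speed_mm_s(self) -> float:
        # forward differences: the final repeated sample is excluded
        n_steps = max(len(self) - 1, 1)
        return float(np.mean(self.speeds_um_s[:n_steps])) / 1000.0


def pixel_centers_um(n: int, pixel_size_um: float) -> np.ndarray:
    """Physical coordinates of pixel centres along one axis."""
    return (np.arange(n) + 0.5) * pixel_size_um


def um_to_index(coord_um: np.ndarray | float, pixel_size_um: float):
    """Continuous array index of a physical coordinate (pixel-centre origin)."""
    return np.asarray(coord_um) / pixel_size_um - 0.5


def index_to_um(index: np.ndarray | float, pixel_size_um: float):
    """Physical coordinate of a continuous array index."""
    return (np.asarray(index) + 0.5) * pixel_size_um
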