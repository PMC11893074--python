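"""Two-stage tissue-motion estimation and CEUS correction.

Motion is estimated on B-mode frames against a reference frame in two
stages: a global affine (translation initialised by phase correlation,
then direct optimisation of normalized cross-correlation), followed by a
nonrigid residual regularised on a coarse cubic B-spline control grid.
The resulting displacement fields are applied in reverse to the CEUS
frames so that microbubbles accumulate at their true positions.

Field convention: a ``DeformationField`` stores, per pixel, the
displacement ``d`` (um, channels ``(dx, dy)``) such that
``moving(x + d(x)) ~= reference(x)``.  Correcting a frame is therefore a
single resampling at ``x + d(x)``; ``invert_displacement_field`` is
provided for forward (material) fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import optical_flow_ilk, phase_cross_correlation

from ulmkit.core import DegenerateInputError, FrameSequence

__all__ = [
    "AffineTransform",
    "DeformationField",
    "ncc",
    "estimate_global_affine",
    "estimate_nonrigid_bspline",
    "estimate_motion",
    "correct_ceus",
    "invert_displacement_field",
]


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation coefficient of two images."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map from reference to moving physical coordinates.

    ``x_mov = linear @ (x_ref - center) + center + translation_um`` with
    ``x = (x_um, y_um)``.  ``center_um`` is the rotation centre (image
    centre by default).
    """

    linear: np.ndarray  # (2, 2), dimensionless
    translation_um: np.ndarray  # (2,) = (dx, dy)
    center_um: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float)
        object.__setattr__(self, "linear", lin)
        object.__setattr__(
            self, "translation_um", np.asarray(self.translation_um, float)
        )
        object.__setattr__(self, "center_um", np.asarray(self.center_um, float))
        if abs(np.linalg.det(lin)) <= 1e-6:
            raise ValueError("affine linear part is (near-)singular")

    @classmethod
    def identity(cls, center_um=(0.0, 0.0)) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2), np.asarray(center_um, float))

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map (N, 2) reference points (x, y) to moving coordinates."""
        p = np.atleast_2d(points_um) - self.center_um
        return p @ self.linear.T + self.center_um + self.translation_um

    def displacement_um(self, shape: tuple[int, int],
                        pixel_size_um: float) -> np.ndarray:
        """Dense pull-back displacement field (H, W, 2) in um."""
        H, W = shape
        ys = (np.arange(H) + 0.5) * pixel_size_um
        xs = (np.arange(W) + 0.5) * pixel_size_um
        grid = np.stack(np.meshgrid(xs, ys), axis=-1)  # (H, W, 2) = (x, y)
        mapped = self.apply(grid.reshape(-1, 2)).reshape(H, W, 2)
        return mapped - grid

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.linear[1, 0],
                                           self.linear[0, 0])))


@dataclass
class DeformationField:
    """Per-pixel pull-back displacement (um) on the coarse grid."""

    displacement_um: np.ndarray  # (H, W, 2), channels (dx, dy)
    frame_index: int = 0
    affine_only: bool = dc_field(default=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_um, dtype=float)
        if d.ndim != 3 or d.shape[2] != 2:
            raise ValueError("displacement must be (H, W, 2)")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement field must be finite")
        self.displacement_um = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement_um.shape[:2]

    def magnitude_um(self) -> np.ndarray:
        return np.linalg.norm(self.displacement_um, axis=-1)


def _warp_by_affine(image: np.ndarray, params: np.ndarray,
                    center_px: np.ndarray) -> np.ndarray:
    """Resample ``image`` at affine-mapped pixel coordinates (pull-back)."""
    a11, a12, a21, a22, tx, ty = params
    H, W = image.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    x = cols - center_px[0]
    y = rows - center_px[1]
    xm = a11 * x + a12 * y + center_px[0] + tx
    ym = a21 * x + a22 * y + center_px[1] + ty
    return ndimage.map_coordinates(image, [ym, xm], order=1, mode="nearest")


def estimate_global_affine(
    reference: np.ndarray,
    moving: np.ndarray,
    pixel_size_um: float = 1.0,
    max_iter: int = 200,
) -> AffineTransform:
    """Global affine registration of ``moving`` onto ``reference``.

    Translation is initialised by subpixel phase correlation, then all six
    affine parameters are refined by Powell search on the normalized
    cross-correlation.  The returned transform never scores worse than the
    unregistered pair.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving frames must share a shape")
    if reference.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("constant image cannot be registered")

    shift, _, _ = phase_cross_correlation(reference, moving,
                                          upsample_factor=20)
    # phase correlation returns the (row, col) shift that moves `moving`
    # onto `reference`; the pull-back displacement is its negation
    init_t = np.array([-shift[1], -shift[0]])  # (tx, ty) in px

    H, W = reference.shape
    center_px = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    x0 = np.array([1.0, 0.0, 0.0, 1.0, init_t[0], init_t[1]])

    def objective(params: np.ndarray) -> float:
        return -ncc(reference, _warp_by_affine(moving, params, center_px))

    res = optimize.minimize(
        objective,
        x0,
        method="Powell",
        options={"maxiter": max_iter, "xtol": 1e-3, "ftol": 1e-6},
    )
    params = res.x if -res.fun >= -objective(x0) else x0

    center_um = (center_px + 0.5) * pixel_size_um
    return AffineTransform(
        linear=np.array([[params[0], params[1]], [params[2], params[3]]]),
        translation_um=np.array([params[4], params[5]]) * pixel_size_um,
        center_um=center_um,
    )


def _bspline_smooth(flow: np.ndarray, spacing_px: int) -> np.ndarray:
    """Project a dense field component onto a cubic B-spline control grid.

    The field is low-pass filtered, sampled on a control grid with the
    given spacing, and re-expanded by cubic spline interpolation — a
    least-squares-flavoured fit that enforces smoothness at the control
    scale.
    """
    from scipy.interpolate import RectBivariateSpline

    H, W = flow.shape
    smoothed = ndimage.gaussian_filter(flow, spacing_px / 2.0, mode="nearest")
    ry = np.unique(np.clip(np.arange(0, H + spacing_px, spacing_px), 0, H - 1))
    rx = np.unique(np.clip(np.arange(0, W + spacing_px, spacing_px), 0, W - 1))
    ctrl = smoothed[np.ix_(ry, rx)]
    kx = 3 if len(rx) > 3 else max(len(rx) - 1, 1)
    ky = 3 if len(ry) > 3 else max(len(ry) - 1, 1)
    spline = RectBivariateSpline(ry, rx, ctrl, kx=ky, ky=kx)
    return spline(np.arange(H), np.arange(W))


def estimate_nonrigid_bspline(
    reference: np.ndarray,
    moving: np.ndarray,
    init: AffineTransform,
    pixel_size_um: float = 1.0,
    control_spacing_px: int = 16,
    flow_radius_px: int = 8,
    frame_index: int = 0,
) -> DeformationField:
    """Nonrigid residual registration on top of an affine initialisation.

    The affine-corrected moving frame is registered to the reference with
    iterative Lucas-Kanade optical flow; the dense flow is regularised on
    a coarse B-spline control grid and composed with the affine field.
    Falls back (with a warning and ``affine_only=True``) if the composed
    field does not improve on the affine similarity.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving frames must share a shape")

    affine_field_um = init.displacement_um(reference.shape, pixel_size_um)
    center_px = np.array([
        (reference.shape[1] - 1) / 2.0,
        (reference.shape[0] - 1) / 2.0,
    ])
    params = np.array([
        init.linear[0, 0], init.linear[0, 1],
        init.linear[1, 0], init.linear[1, 1],
        init.translation_um[0] / pixel_size_um,
        init.translation_um[1] / pixel_size_um,
    ])
    moving_affine = _warp_by_affine(moving, params, center_px)
    score_affine = ncc(reference, moving_affine)

    flow = optical_flow_ilk(reference, moving_affine, radius=flow_radius_px)
    dy = _bspline_smooth(flow[0], control_spacing_px)
    dx = _bspline_smooth(flow[1], control_spacing_px)

    total_um = affine_field_um + np.stack([dx, dy], axis=-1) * pixel_size_um
    field = DeformationField(total_um, frame_index=frame_index)

    corrected = _resample_with_field(moving, field, pixel_size_um)
    if ncc(reference, corrected) < score_affine - 1e-6:
        warnings.warn(
            "nonrigid refinement did not improve similarity; "
            "falling back to affine-only field",
            stacklevel=2,
        )
        return DeformationField(affine_field_um, frame_index=frame_index,
                                affine_only=True)
    return field


def _resample_with_field(frame: np.ndarray, field: DeformationField,
                         pixel_size_um: float, order: int = 1) -> np.ndarray:
    H, W = frame.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    d_px = field.displacement_um / pixel_size_um
    return ndimage.map_coordinates(
        frame, [rows + d_px[..., 1], cols + d_px[..., 0]],
        order=order, mode="nearest",
    )


def estimate_motion(
    bmode: FrameSequence,
    reference_index: int = 0,
    mode: str = "affine+bspline",
    control_spacing_px: int = 16,
) -> list[DeformationField]:
    """Estimate one displacement field per frame against a reference frame.

    ``mode`` selects the pipeline stage depth: ``"affine"`` stops after
    the global stage, ``"affine+bspline"`` adds the nonrigid residual.
    The reference frame gets an exact zero field.
    """
    if mode not in ("affine", "affine+bspline"):
        raise ValueError(f"unknown registration mode {mode!r}")
    reference = bmode.frames[reference_index]
    px = bmode.pixel_size_um
    fields: list[DeformationField] = []
    for t in range(bmode.n_frames):
        if t == reference_index:
            fields.append(
                DeformationField(
                    np.zeros((*bmode.frame_shape, 2)), frame_index=t
                )
            )
            continue
        aff = estimate_global_affine(reference, bmode.frames[t],
                                     pixel_size_um=px)
        if mode == "affine":
            fields.append(
                DeformationField(
                    aff.displacement_um(bmode.frame_shape, px), frame_index=t
                )
            )
        else:
            fields.append(
                estimate_nonrigid_bspline(
                    reference, bmode.frames[t], aff, pixel_size_um=px,
                    control_spacing_px=control_spacing_px, frame_index=t,
                )
            )
    return fields


def correct_ceus(
    ceus: FrameSequence,
    fields: list[DeformationField],
    order: int = 1,
) -> FrameSequence:
    """Resample each CEUS frame by its (reversed) displacement field.

    After correction, scene content that was static in the reference frame
    becomes stationary across the whole sequence.
    """
    if len(fields) != ceus.n_frames:
        raise ValueError(
            f"need one field per frame ({ceus.n_frames}), got {len(fields)}"
        )
    out = np.empty_like(ceus.frames)
    for t, field in enumerate(fields):
        if field.shape != ceus.frame_shape:
            raise ValueError(
                f"field {t} shape {field.shape} != frame shape "
                f"{ceus.frame_shape}"
            )
        if not np.any(field.displacement_um):
            out[t] = ceus.frames[t]
        else:
            out[t] = _resample_with_field(ceus.frames[t], field,
                                          ceus.pixel_size_um, order=order)
    return FrameSequence(out, ceus.pixel_size_um, ceus.frame_rate_hz,
                         channel=ceus.channel)


def invert_displacement_field(
    field: DeformationField,
    pixel_size_um: float,
    n_iter: int = 3,
) -> DeformationField:
    """Invert a forward displacement field by fixed-point iteration.

    Solves ``d_inv(x) = -d(x + d_inv(x))``; with ``n_iter=0`` this reduces
    to plain negation (adequate for small, smooth motion).
    """
    d = field.displacement_um
    H, W = d.shape[:2]
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    d_inv = -d.copy()
    for _ in range(n_iter):
        sample_r = rows + d_inv[..., 1] / pixel_size_um
        sample_c = cols + d_inv[..., 0] / pixel_size_um
        dx = ndimage.map_coordinates(d[..., 0], [sample_r, sample_c],
                                     order=1, mode="nearest")
        dy = ndimage.map_coordinates(d[..., 1], [sample_r, sample_c],
                                     order=1, mode="nearest")
        d_inv = -np.stack([dx, dy], axis=-1)
    return DeformationField(d_inv, frame_index=field.frame_index)
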