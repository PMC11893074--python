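"""End-to-end orchestration: frames -> motion correction -> localization
-> tracking -> maps -> metrics, with config and standard-format I/O."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

import ulmkit
from ulmkit import localization as loc_mod
from ulmkit import mapping as map_mod
from ulmkit import morphometrics as morph_mod
from ulmkit import motion_correction as mc_mod
from ulmkit import tracking as trk_mod
from ulmkit.core import (
    AcquisitionConfig,
    DegenerateInputError,
    FrameSequence,
    Localization,
    Track,
)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineStageError",
    "run_pipeline",
    "read_acquisition",
    "split_side_by_side",
    "tracks_to_dataframe",
    "localizations_to_dataframe",
]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error raised inside a pipeline stage, tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Full run configuration; round-trips through a single YAML file."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    registration_mode: str = "affine+bspline"  # none | affine | affine+bspline
    reference_index: int = 0
    control_spacing_px: int = 16
    detection_threshold: float = 0.6
    psf_expected_sigma_um: float = 100.0
    psf_noise_floor: float = 0.3
    psf_n_samples: int = 30
    tracking: trk_mod.TrackingParams = field(
        default_factory=trk_mod.TrackingParams
    )
    smoothing: dict = field(default_factory=lambda: {"gaussian_sigma_um": 4.0})
    binarization_threshold: float | None = None  # None => half-max segmentation
    min_component_px: int = 5
    mask_closing_px: int = 4
    mask_erosion_px: int = 1
    roi_path: str | None = None
    output_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acquisition"] = dataclasses.asdict(self.acquisition)
        d["tracking"] = dataclasses.asdict(self.tracking)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        acq = d.pop("acquisition", {})
        if isinstance(acq, dict):
            if "field_of_view" in acq:
                acq["field_of_view"] = tuple(acq["field_of_view"])
            acq = AcquisitionConfig(**acq)
        trk = d.pop("tracking", {})
        if isinstance(trk, dict):
            trk = trk_mod.TrackingParams(**trk)
        return cls(acquisition=acq, tracking=trk, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    metrics: morph_mod.VascMetrics | None
    metrics_available: bool
    counts: dict
    config: dict
    version: str
    wall_time_s: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "metrics": self.metrics.as_dict() if self.metrics else None,
            "metrics_available": self.metrics_available,
            "counts": self.counts,
            "config": self.config,
            "version": self.version,
            "wall_time_s": round(self.wall_time_s, 3),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineStageError(f"stage '{name}': {exc}") from exc
        return wrapper
    return deco


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append((tr.track_id, int(tr.frames[k]), tr.x_um[k],
                         tr.y_um[k], tr.vx_um_s[k], tr.vy_um_s[k]))
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um",
                       "vx_um_s", "vy_um_s"]
    )


def localizations_to_dataframe(
    localizations: list[list[Localization]],
) -> pd.DataFrame:
    rows = [
        (loc.frame, loc.x_um, loc.y_um, loc.score)
        for frame_locs in localizations
        for loc in frame_locs
    ]
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "score"])


def _write_outputs(out_dir: Path, maps: map_mod.ULMMaps | None,
                   tracks: list[Track],
                   localizations: list[list[Localization]],
                   report: RunReport) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    localizations_to_dataframe(localizations).to_csv(
        out_dir / "localizations.csv", index=False, float_format="%.6g"
    )
    tracks_to_dataframe(tracks).to_csv(
        out_dir / "tracks.csv", index=False, float_format="%.6g"
    )
    if maps is not None:
        tifffile.imwrite(out_dir / "density.tif",
                         maps.density.astype(np.float32))
        tifffile.imwrite(out_dir / "velocity_mm_s.tif",
                         maps.velocity_mm_s.astype(np.float32))
        tifffile.imwrite(out_dir / "direction_rad.tif",
                         maps.direction_rad.astype(np.float32))
        tifffile.imwrite(out_dir / "mask.tif",
                         (maps.mask * 255).astype(np.uint8))
        _write_png(out_dir / "density.png", maps.density)
        _write_png(out_dir / "velocity.png", maps.velocity_mm_s)
    report.to_json(out_dir / "report.json")


def _write_png(path: Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    m = image.max()
    scaled = (255 * image / m).astype(np.uint8) if m > 0 else np.zeros(
        image.shape, np.uint8
    )
    iio.imwrite(path, scaled)


def run_pipeline(
    bmode: FrameSequence | None,
    ceus: FrameSequence,
    config: PipelineConfig,
    output_dir: str | Path | None = None,
) -> RunReport:
    """Execute every stage in acquisition order and emit a run report.

    ``bmode`` may be ``None`` only when ``registration_mode == "none"``.
    The analysis path contains no randomness, so reruns with identical
    inputs and config are bit-identical.
    """
    t_start = time.perf_counter()
    acq = config.acquisition
    if bmode is not None and bmode.frames.shape != ceus.frames.shape:
        raise ValueError(
            "precondition failed: B-mode and CEUS stacks must share "
            f"shape (got {bmode.frames.shape} vs {ceus.frames.shape})"
        )
    if config.registration_mode != "none" and bmode is None:
        raise ValueError("registration requires a B-mode channel")

    corrected = ceus
    if config.registration_mode != "none":
        fields = _stage("motion_estimation")(mc_mod.estimate_motion)(
            bmode,
            reference_index=config.reference_index,
            mode=config.registration_mode,
            control_spacing_px=config.control_spacing_px,
        )
        corrected = _stage("motion_correction")(mc_mod.correct_ceus)(
            ceus, fields
        )
        logger.info("motion correction done (%d fields)", len(fields))

    normalized = _stage("normalization")(loc_mod.normalize_sequence)(corrected)
    try:
        psf = loc_mod.estimate_psf(
            normalized,
            acq,
            n_samples=config.psf_n_samples,
            noise_floor=config.psf_noise_floor,
            expected_sigma_um=config.psf_expected_sigma_um,
        )
    except DegenerateInputError:
        logger.warning(
            "no usable blobs for PSF estimation; using parametric Gaussian"
        )
        psf = loc_mod.gaussian_psf(config.psf_expected_sigma_um,
                                   acq.fine_pixel_um)
    localizations = _stage("localization")(loc_mod.localize_sequence)(
        normalized, psf, acq, threshold=config.detection_threshold
    )
    n_locs = sum(len(f) for f in localizations)
    logger.info("localized %d bubbles over %d frames", n_locs,
                len(localizations))

    track_params = dataclasses.replace(config.tracking, min_track_length=1)
    formed = _stage("tracking")(trk_mod.link_tracks)(
        localizations, acq.frame_rate_hz, track_params
    )
    keep_n = config.tracking.min_track_length
    tracks = [t for t in formed if len(t) >= keep_n]
    logger.info("tracks: %d formed, %d kept", len(formed), len(tracks))

    maps = None
    metrics = None
    roi = None
    if config.roi_path:
        roi = tifffile.imread(config.roi_path).astype(bool)
    if tracks:
        maps = _stage("mapping")(map_mod.build_maps)(
            tracks,
            acq,
            smoothing=config.smoothing,
            threshold_count=config.binarization_threshold,
            min_area_px=config.min_component_px,
            closing_radius_px=config.mask_closing_px,
            erosion_px=config.mask_erosion_px,
        )
        metrics = _stage("morphometrics")(morph_mod.compute_metrics)(
            tracks, maps, acq, roi=roi
        )
    else:
        logger.warning("no tracks survived filtering; metrics unavailable")

    report = RunReport(
        metrics=metrics,
        metrics_available=metrics is not None,
        counts={
            "frames": ceus.n_frames,
            "localizations": n_locs,
            "tracks_formed": len(formed),
            "tracks_kept": len(tracks),
            "tracks_discarded": len(formed) - len(tracks),
            "psf_fallback": bool(psf.fitted_fallback),
        },
        config=config.to_dict(),
        version=ulmkit.__version__,
        wall_time_s=time.perf_counter() - t_start,
    )
    out = output_dir or config.output_dir
    if out is not None:
        _write_outputs(Path(out), maps, tracks, localizations, report)
    return report


def split_side_by_side(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split (T, H, 2W) frames into left (B-mode) and right (CEUS) halves."""
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    width = frames.shape[2]
    if width % 2:
        raise ValueError("side-by-side frames must have even width")
    half = width // 2
    return frames[:, :, :half], frames[:, :, half:]


def read_acquisition(
    path: str | Path | tuple[str | Path, str | Path],
    layout: str,
    config: PipelineConfig,
) -> tuple[FrameSequence, FrameSequence]:
    """Load a (B-mode, CEUS) pair from disk.

    ``layout="two_tiffs"`` expects ``path`` to be a (bmode, ceus) pair of
    TIFF stacks of equal shape; ``layout="side_by_side_avi"`` decodes a
    video whose frames hold the two channels in two columns (best-effort,
    codec-dependent).
    """
    acq = config.acquisition
    if layout == "two_tiffs":
        p_bmode, p_ceus = path  # type: ignore[misc]
        bmode = np.asarray(tifffile.imread(str(p_bmode)), dtype=float)
        ceus = np.asarray(tifffile.imread(str(p_ceus)), dtype=float)
        if bmode.ndim == 2:
            bmode = bmode[None]
        if ceus.ndim == 2:
            ceus = ceus[None]
        if bmode.shape != ceus.shape:
            raise ValueError(
                f"channel shapes differ: {bmode.shape} vs {ceus.shape}"
            )
    elif layout == "side_by_side_avi":
        import imageio.v3 as iio

        try:
            frames = np.asarray(iio.imread(str(path)), dtype=float)
        except Exception as exc:
            raise ValueError(f"cannot decode video {path}: {exc}") from exc
        if frames.ndim == 4:  # RGB(A) -> luminance
            frames = frames[..., :3].mean(axis=-1)
        bmode, ceus = split_side_by_side(frames)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return (
        FrameSequence(bmode, acq.pixel_size_um, acq.frame_rate_hz, "bmode"),
        FrameSequence(ceus, acq.pixel_size_um, acq.frame_rate_hz, "ceus"),
    )
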