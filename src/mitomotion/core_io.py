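"""Domain types, calibration handling, and movie/table I/O.

The pipeline works on calibrated single-channel time-lapse stacks: a stack
of 2-D intensity rasters together with a spatial calibration (µm per pixel)
and a temporal calibration (seconds per frame).  All downstream modules
express positions in µm, areas in µm² and speeds in µm/s; the conversion is
always an exact multiplication by the calibration factors.

Coordinate convention: pixel centers sit at integer coordinates, the origin
is the center of the top-left pixel of the first frame, ``x`` indexes
columns and ``y`` indexes rows.  Exported physical coordinates are µm from
this origin.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "CalibratedMovie",
    "PipelineConfig",
    "read_movie",
    "write_movie",
    "write_tables",
    "write_run_manifest",
]


class CalibrationError(ValueError):
    """Raised when no valid spatial/temporal calibration can be determined."""


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal scale of a movie.

    Parameters
    ----------
    pixel_size:
        Physical edge length of one pixel, µm/px.  Must be > 0.
    frame_interval:
        Time between consecutive frames, s.  Must be > 0.
    """

    pixel_size: float
    frame_interval: float = 4.0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise CalibrationError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )

    def px_to_um(self, value_px: float | np.ndarray) -> float | np.ndarray:
        return value_px * self.pixel_size

    def um_to_px(self, value_um: float | np.ndarray) -> float | np.ndarray:
        return value_um / self.pixel_size

    def frames_to_seconds(self, n_frames: float) -> float:
        return n_frames * self.frame_interval


@dataclass
class CalibratedMovie:
    """An ordered stack of equally shaped 2-D frames with calibration."""

    frames: np.ndarray  # (t, h, w)
    calibration: Calibration
    name: str = "movie"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (t, h, w) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("movie needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def duration(self) -> float:
        """Elapsed time from first to last frame, s."""
        return (self.n_frames - 1) * self.calibration.frame_interval

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with the faithful defaults.

    The defaults reproduce the published analysis settings: LoG blob
    diameter 1.5 µm with quality threshold 1.0, frame-to-frame linking at
    2 µm with gap closing off, a strict > 1.5 µm track-displacement filter
    for motility, and a particle-area gate that excludes components
    strictly below 0.2 µm² or strictly above 5 µm², measured on the first
    frame of the sequence.
    """

    blob_diameter: float = 1.5  # µm
    quality_threshold: float = 1.0  # detector-response units
    max_link_distance: float = 2.0  # µm
    gap_closing: bool = False  # fixed off in the faithful preset
    min_track_displacement: float = 1.5  # µm; strict "above"
    min_particle_area: float = 0.2  # µm²; inclusive bound
    max_particle_area: float = 5.0  # µm²; inclusive bound
    morphology_frame_index: int = 0
    threshold_method: str | float = "otsu"
    # Whether speed summary statistics are restricted to motile tracks
    # (tracks passing the displacement filter).  Displacement statistics
    # are always over motile tracks.
    speed_on_motile_only: bool = True
    # Denominator of the motile fraction: "particles" (first-frame gated
    # particle count) or "tracks" (all tracks).
    motile_fraction_denominator: str = "particles"

    def __post_init__(self) -> None:
        for name in (
            "blob_diameter",
            "quality_threshold",
            "max_link_distance",
            "min_track_displacement",
            "min_particle_area",
            "max_particle_area",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("blob_diameter", "max_link_distance", "min_particle_area",
                     "max_particle_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.min_particle_area < self.max_particle_area:
            raise ValueError("min_particle_area must be < max_particle_area")
        if self.motile_fraction_denominator not in ("particles", "tracks"):
            raise ValueError(
                "motile_fraction_denominator must be 'particles' or 'tracks'"
            )

    @classmethod
    def paper2023(cls) -> "PipelineConfig":
        """The published preset; identical to the dataclass defaults."""
        return cls()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# ---------------------------------------------------------------------------
# movie I/O


def _calibration_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Pull (pixel_size µm/px, frame_interval s) out of TIFF metadata.

    Understands the ImageJ convention written by :func:`write_movie`:
    XResolution in pixels per unit, unit given by the ImageJ metadata
    (assumed µm), and ``finterval`` for the frame interval.
    """
    pixel_size = None
    frame_interval = None
    ij = tif.imagej_metadata or {}
    unit = ij.get("unit")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is not None and unit in ("um", "micron", "µm"):
        num, den = xres.value
        if num:
            pixel_size = den / num  # resolution is px per unit
    finterval = ij.get("finterval")
    if finterval:
        frame_interval = float(finterval)
    return pixel_size, frame_interval


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    name: str | None = None,
) -> CalibratedMovie:
    """Read a single-channel multi-page TIFF into a :class:`CalibratedMovie`.

    Explicit ``pixel_size`` / ``frame_interval`` arguments take precedence
    over TIFF metadata; calibration is never guessed.  Raises
    :class:`CalibrationError` if neither source provides a value, and
    ``ValueError`` for multi-channel (RGB) input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px, meta_dt = _calibration_from_tiff(tif)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"expected a single-channel 2-D time series, got shape {data.shape}"
        )
    # RGB pages come out as (..., 3) or (..., 4); a trailing small axis after
    # a 2-D page is a channel axis, not time.
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise ValueError("multi-channel/RGB TIFF input is not supported")
    px = pixel_size if pixel_size is not None else meta_px
    dt = frame_interval if frame_interval is not None else meta_dt
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel size given and none found in TIFF metadata"
        )
    if dt is None:
        raise CalibrationError(
            f"{path}: no frame interval given and none found in TIFF metadata"
        )
    return CalibratedMovie(
        frames=data,
        calibration=Calibration(pixel_size=float(px), frame_interval=float(dt)),
        name=name or path.stem,
    )


def write_movie(movie: CalibratedMovie, path: str | Path) -> Path:
    """Write a movie as an ImageJ-flavoured multi-page grayscale TIFF.

    Pixel size is stored in the resolution tags (px per µm) and the frame
    interval in the ImageJ metadata, so :func:`read_movie` round-trips the
    calibration without explicit arguments.
    """
    path = Path(path)
    cal = movie.calibration
    res = 1.0 / cal.pixel_size
    data = movie.frames
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "finterval": cal.frame_interval, "axes": "TYX"},
    )
    return path


# ---------------------------------------------------------------------------
# tabular output

SPOTS_COLUMNS = ["frame", "x_um", "y_um", "quality"]
TRACKS_COLUMNS = [
    "track_id",
    "n_spots",
    "first_frame",
    "last_frame",
    "displacement_um",
    "mean_speed_um_per_s",
    "motile",
]
MORPHOLOGY_COLUMNS = [
    "particle_id",
    "area_um2",
    "feret_um",
    "aspect_ratio",
    "centroid_x_um",
    "centroid_y_um",
]


def _spots_frame(spots: Iterable) -> pd.DataFrame:
    rows = [
        {"frame": s.frame, "x_um": s.x, "y_um": s.y, "quality": s.quality}
        for s in spots
    ]
    df = pd.DataFrame(rows, columns=SPOTS_COLUMNS)
    if len(df):
        df = df.sort_values(["frame", "y_um", "x_um"], kind="mergesort")
    return df.reset_index(drop=True)


def _tracks_frame(tracks: Iterable, config: PipelineConfig,
                  frame_interval: float) -> pd.DataFrame:
    from . import tracking  # local import to avoid a cycle

    rows = []
    for t in tracks:
        disp = tracking.track_displacement(t)
        rows.append(
            {
                "track_id": t.track_id,
                "n_spots": len(t.spots),
                "first_frame": t.spots[0].frame,
                "last_frame": t.spots[-1].frame,
                "displacement_um": disp,
                "mean_speed_um_per_s": tracking.track_mean_speed(t, frame_interval),
                "motile": int(disp > config.min_track_displacement),
            }
        )
    df = pd.DataFrame(rows, columns=TRACKS_COLUMNS)
    if len(df):
        df = df.sort_values(["first_frame", "track_id"], kind="mergesort")
    return df.reset_index(drop=True)


def _particles_frame(particles: Iterable) -> pd.DataFrame:
    rows = [
        {
            "particle_id": p.particle_id,
            "area_um2": p.area,
            "feret_um": p.feret_diameter,
            "aspect_ratio": p.aspect_ratio,
            "centroid_x_um": p.centroid[0],
            "centroid_y_um": p.centroid[1],
        }
        for p in particles
    ]
    df = pd.DataFrame(rows, columns=MORPHOLOGY_COLUMNS)
    if len(df):
        df = df.sort_values(["centroid_y_um", "centroid_x_um"], kind="mergesort")
    return df.reset_index(drop=True)


def write_tables(
    spots: Sequence,
    tracks: Sequence,
    particles: Sequence,
    summaries: pd.DataFrame | None,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    frame_interval: float = 4.0,
) -> dict[str, Path]:
    """Write spots/tracks/morphology/roi_summary CSV files.

    Lengths are µm, areas µm², speeds µm/s.  Row order is deterministic
    (frame, then y, then x for spots; analogous keys elsewhere), so two
    runs on the same inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    paths = {}

    tables = {
        "spots": _spots_frame(spots),
        "tracks": _tracks_frame(tracks, config, frame_interval),
        "morphology": _particles_frame(particles),
    }
    if summaries is None:
        summaries = pd.DataFrame()
    tables["roi_summary"] = summaries

    for stem, df in tables.items():
        p = out_dir / f"{stem}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths[stem] = p
    return paths


def write_run_manifest(
    out_dir: str | Path,
    config: PipelineConfig,
    inputs: dict | None = None,
) -> Path:
    """Write a JSON manifest of the full configuration for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "mitomotion",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": inputs or {},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
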