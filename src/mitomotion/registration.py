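"""Global X/Y drift estimation and correction for image stacks.

Live tissue slices drift under the objective; before tracking, every frame
is registered to the first by a pure translation.  Drift is estimated
sequentially (frame *i* against frame *i−1*) because photobleaching makes
distant frame pairs dissimilar, and the per-pair offsets are accumulated
relative to frame 0.  Each pairwise offset maximizes the intensity
cross-correlation (computed by FFT after light smoothing), refined to
sub-pixel precision by locally upsampling the correlation peak.  Rotation
and non-rigid deformation are out of scope: the correction model is
translation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core_io import CalibratedMovie

__all__ = ["DriftTrace", "estimate_drift", "apply_correction", "write_drift"]


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) offsets in pixels relative to frame 0.

    ``offsets[i]`` is the displacement of the content of frame *i* with
    respect to frame 0; frame 0 has offset exactly (0, 0).  Offsets may be
    fractional.
    """

    offsets: np.ndarray  # (t, 2) as (dx, dy)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must have shape (t, 2)")
        if not np.allclose(self.offsets[0], 0.0):
            raise ValueError("offset of frame 0 must be (0, 0)")

    def __len__(self) -> int:
        return len(self.offsets)


_SMOOTH_SIGMA_PX = 1.0  # pre-smoothing scale for noise suppression


def _pair_offset(ref: np.ndarray, mov: np.ndarray) -> tuple[float, float]:
    """Offset (dx, dy) of ``mov`` relative to ``ref`` by cross-correlation.

    Both frames are lightly Gaussian-smoothed (sigma 1 px, circular
    boundary) to suppress pixel noise, mean-subtracted, and registered by
    FFT cross-correlation with local upsampling of the correlation peak
    for sub-pixel precision.
    """
    if ref.shape != mov.shape:
        raise ValueError(f"frame shape mismatch: {ref.shape} vs {mov.shape}")
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    # ignore border rows/columns that are zero-filled in either frame
    # (left behind by an earlier correction pass); they would otherwise
    # act as a strong spurious feature locked to the frame edges
    valid = (ref != 0) & (mov != 0)
    rows = np.nonzero(valid.any(axis=1))[0]
    cols = np.nonzero(valid.any(axis=0))[0]
    if len(rows) == 0 or len(cols) == 0:
        return 0.0, 0.0
    if (rows[0], rows[-1]) != (0, ref.shape[0] - 1) or (
        cols[0], cols[-1]
    ) != (0, ref.shape[1] - 1):
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        ref = ref[sl]
        mov = mov[sl]
    a = ndimage.gaussian_filter(
        np.asarray(ref, dtype=float), _SMOOTH_SIGMA_PX, mode="wrap"
    )
    b = ndimage.gaussian_filter(
        np.asarray(mov, dtype=float), _SMOOTH_SIGMA_PX, mode="wrap"
    )
    a -= a.mean()
    b -= b.mean()
    shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=200, normalization=None
    )
    # shift registers `mov` onto `ref`; the drift of `mov` is its negation
    return float(-shift[1]), float(-shift[0])


def estimate_drift(movie: CalibratedMovie) -> DriftTrace:
    """Estimate cumulative translation drift of every frame vs frame 0."""
    frames = movie.frames
    offsets = np.zeros((movie.n_frames, 2), dtype=float)
    for i in range(1, movie.n_frames):
        dx, dy = _pair_offset(frames[i - 1], frames[i])
        offsets[i] = offsets[i - 1] + (dx, dy)
    return DriftTrace(offsets=offsets)


def apply_correction(movie: CalibratedMovie, drift: DriftTrace) -> CalibratedMovie:
    """Resample every frame by the negated drift offset (bilinear, zero fill).

    Out-of-field pixels are set to 0; the calibration is unchanged.
    """
    if len(drift) != movie.n_frames:
        raise ValueError(
            f"drift length {len(drift)} != frame count {movie.n_frames}"
        )
    corrected = np.empty_like(movie.frames, dtype=float)
    for i in range(movie.n_frames):
        dx, dy = drift.offsets[i]
        if dx == 0 and dy == 0:
            corrected[i] = movie.frames[i]
        else:
            # ndimage.shift moves content by +s: undoing drift (dx, dy)
            # means shifting by (-dy, -dx) in (row, col) order
            corrected[i] = ndimage.shift(
                movie.frames[i].astype(float),
                shift=(-dy, -dx),
                order=1,
                mode="constant",
                cval=0.0,
            )
    return CalibratedMovie(
        frames=corrected, calibration=movie.calibration, name=movie.name
    )


def write_drift(drift: DriftTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(drift)),
            "dx_px": drift.offsets[:, 0],
            "dy_px": drift.offsets[:, 1],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")
    return path
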