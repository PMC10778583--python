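"""Laplacian-of-Gaussian blob detection with sub-pixel localization.

Mitochondria appear as bright, roughly diffraction-limited blobs.  Each
frame is filtered with a negated, scale-normalized Laplacian of Gaussian
whose scale is matched to a nominal blob diameter ``d``:

    sigma = (d / 2) / sqrt(2)

(the scale at which an ideal blob of diameter ``d`` maximizes the
normalized response).  Detections are strict 8-neighbourhood local maxima
of the response whose value — the spot *quality* — reaches the configured
quality threshold.  Maxima closer than one blob radius are reduced to the
single best one, and the surviving peaks are localized to sub-pixel
precision by a quadratic fit of the 3×3 response neighbourhood.

Quality is the raw normalized response: it scales linearly with image
intensity and is therefore tied to acquisition settings (bit depth, laser
power); the threshold is a free parameter of the run configuration.
"""

from __future__ import annotations

import math
from functools import lru_cache
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Calibration, PipelineConfig

__all__ = ["Spot", "log_sigma_px", "log_response", "detect_spots"]


@dataclass(frozen=True)
class Spot:
    """One detection: frame index, sub-pixel centroid in µm, quality."""

    frame: int
    x: float
    y: float
    quality: float

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def log_sigma_px(blob_diameter: float, calibration: Calibration) -> float:
    """Gaussian scale in pixels for a nominal blob diameter in µm."""
    radius_um = blob_diameter / 2.0
    return (radius_um / math.sqrt(2.0)) / calibration.pixel_size


def log_response(
    frame: np.ndarray, blob_diameter: float, calibration: Calibration
) -> np.ndarray:
    """Negated scale-normalized LoG response of one frame.

    Bright round blobs of the nominal diameter produce positive local
    maxima.  The response is multiplied by sigma² (scale normalization) so
    that blobs of the matched size respond independently of the pixel
    grid.  Filtering uses reflect padding.
    """
    if blob_diameter <= 0:
        raise ValueError("blob_diameter must be > 0")
    diameter_px = blob_diameter / calibration.pixel_size
    if diameter_px < 2.0:
        raise ValueError(
            f"blob diameter {blob_diameter} µm is {diameter_px:.2f} px at "
            f"{calibration.pixel_size} µm/px; need >= 2 px"
        )
    sigma = log_sigma_px(blob_diameter, calibration)
    frame = np.asarray(frame, dtype=float)
    resp = -ndimage.gaussian_laplace(frame, sigma=sigma, mode="reflect")
    # the truncated discrete kernel does not sum exactly to zero; subtract
    # its response to a smoothed copy so constants map exactly to zero
    leak = _kernel_leak(sigma)
    if leak != 0.0:
        resp += leak * ndimage.gaussian_filter(frame, sigma=sigma, mode="reflect")
    return resp * sigma**2


def noise_response_sd(noise_sd: float, sigma: float) -> float:
    """Standard deviation of the normalized LoG response to white noise.

    For i.i.d. Gaussian pixel noise the response sd is the noise sd times
    the L2 norm of the (scale-normalized) filter kernel.
    """
    return noise_sd * _kernel_l2(sigma) * sigma**2


@lru_cache(maxsize=32)
def _kernel_l2(sigma: float) -> float:
    """L2 norm of the discrete Gaussian-Laplace impulse response."""
    half = int(math.ceil(4.0 * sigma)) + 2
    size = 2 * half + 1
    impulse = np.zeros((size, size))
    impulse[half, half] = 1.0
    kernel = ndimage.gaussian_laplace(impulse, sigma=sigma, mode="constant")
    return float(np.sqrt((kernel**2).sum()))


@lru_cache(maxsize=32)
def _kernel_leak(sigma: float) -> float:
    """Response of the discrete Gaussian-Laplace kernel to a unit constant."""
    half = int(math.ceil(4.0 * sigma)) + 1
    size = 2 * half + 1
    value = ndimage.gaussian_laplace(
        np.ones((size, size)), sigma=sigma, mode="reflect"
    )[half, half]
    return float(value)


def _quadratic_subpixel(patch: np.ndarray) -> tuple[float, float]:
    """(dx, dy) vertex offset of a 2-D quadratic fit to a 3×3 patch.

    The full quadratic (including the cross term) is fit by least squares
    so that elongated, rotated peaks localize without axis bias; the
    vertex is clipped to the patch footprint.
    """
    z = np.asarray(patch, dtype=float)
    b = (z[:, 2].sum() - z[:, 0].sum()) / 6.0  # d/dx
    c = (z[2, :].sum() - z[0, :].sum()) / 6.0  # d/dy
    d = (z[:, 0].sum() - 2.0 * z[:, 1].sum() + z[:, 2].sum()) / 6.0  # x²
    f = (z[0, :].sum() - 2.0 * z[1, :].sum() + z[2, :].sum()) / 6.0  # y²
    e = (z[2, 2] - z[2, 0] - z[0, 2] + z[0, 0]) / 4.0  # xy
    det = 4.0 * d * f - e * e
    if det == 0:
        return 0.0, 0.0
    dx = (-2.0 * f * b + e * c) / det
    dy = (-2.0 * d * c + e * b) / det
    return (
        float(np.clip(dx, -0.5, 0.5)),
        float(np.clip(dy, -0.5, 0.5)),
    )


def detect_spots(
    frame: np.ndarray,
    config: PipelineConfig,
    calibration: Calibration,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect spots in one frame; coordinates are exported in µm.

    Strict local maxima of the LoG response are thresholded at
    ``config.quality_threshold``; peaks closer than one blob radius are
    merged keeping the higher quality (ties broken toward smaller (y, x)
    pixel position); maxima whose 3×3 neighbourhood leaves the image are
    discarded.
    """
    resp = log_response(frame, config.blob_diameter, calibration)
    h, w = resp.shape

    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = ndimage.maximum_filter(resp, footprint=footprint, mode="reflect")
    is_max = (resp > neighbour_max) & (resp >= config.quality_threshold)
    # drop peaks whose 3×3 neighbourhood leaves the image
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False

    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return []
    qualities = resp[ys, xs]

    # non-maximum suppression within one blob radius; higher quality wins,
    # ties broken by smaller (y, x)
    order = np.lexsort((xs, ys, -qualities))
    radius_px = (config.blob_diameter / 2.0) / calibration.pixel_size
    r2 = radius_px**2
    kept: list[int] = []
    for idx in order:
        y, x = ys[idx], xs[idx]
        if all((y - ys[k]) ** 2 + (x - xs[k]) ** 2 >= r2 for k in kept):
            kept.append(idx)

    px = calibration.pixel_size
    spots = []
    for idx in kept:
        y, x = int(ys[idx]), int(xs[idx])
        dx, dy = _quadratic_subpixel(resp[y - 1 : y + 2, x - 1 : x + 2])
        spots.append(
            Spot(
                frame=frame_index,
                x=(x + dx) * px,
                y=(y + dy) * px,
                quality=float(qualities[idx]),
            )
        )
    spots.sort(key=lambda s: (s.y, s.x))
    return spots
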