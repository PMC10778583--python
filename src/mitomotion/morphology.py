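"""First-frame binary morphometry: segmentation, size gating, shape features.

Morphology is measured on a single frame (the first by default): the frame
is thresholded (Otsu by default, or a user-fixed value, since absolute
intensities vary between acquisitions), 8-connected components are
extracted, components outside the configured area gate are discarded, and
each surviving particle is described by

* area — pixel count × pixel_size², µm²;
* Feret's diameter — maximum caliper extent, i.e. the maximum pairwise
  distance over the component's pixel *corner* points (so a single pixel
  has Feret √2·pixel_size, not 0), µm;
* aspect ratio — major/minor axis ratio of the moment-fit ellipse, 1 for
  a circle, growing with elongation.

The aspect ratio uses intensity-unweighted second-order central moments of
the pixel centers with a uniform-pixel correction of 1/12 px² added to
both diagonal terms.  The correction accounts for each pixel's own extent:
it makes an a×b pixel rectangle come out exactly at a/b and keeps
single-pixel-wide (collinear) components finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_otsu

from .core_io import CalibratedMovie, Calibration, PipelineConfig

__all__ = [
    "Particle",
    "select_morphology_frame",
    "segment",
    "extract_particles",
    "feret_diameter",
    "aspect_ratio",
]


@dataclass(frozen=True)
class Particle:
    """One gated connected component of the morphology frame."""

    particle_id: int
    area: float  # µm²
    feret_diameter: float  # µm
    aspect_ratio: float  # dimensionless, >= 1
    centroid: tuple[float, float]  # (x, y) µm


def select_morphology_frame(
    movie: CalibratedMovie, config: PipelineConfig
) -> np.ndarray:
    """The frame used for morphometry (first frame by default)."""
    idx = config.morphology_frame_index
    if not 0 <= idx < movie.n_frames:
        raise IndexError(
            f"morphology_frame_index {idx} out of range for "
            f"{movie.n_frames}-frame movie"
        )
    return movie.frame(idx)


def segment(frame: np.ndarray, threshold_method: str | float = "otsu") -> np.ndarray:
    """Binary foreground mask: pixels with intensity >= threshold.

    ``threshold_method`` is either the name ``"otsu"`` or a fixed numeric
    threshold.  A constant frame cannot be Otsu-thresholded; the error
    instructs using a fixed value instead.
    """
    frame = np.asarray(frame)
    if isinstance(threshold_method, str):
        if threshold_method.lower() != "otsu":
            raise ValueError(f"unknown threshold method: {threshold_method!r}")
        if np.all(frame == frame.flat[0]):
            raise ValueError(
                "constant frame: Otsu thresholding is undefined; "
                "pass a fixed numeric threshold instead"
            )
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold_method)
    return frame >= thr


def feret_diameter(coords: np.ndarray, calibration: Calibration) -> float:
    """Maximum caliper diameter of a pixel set, µm.

    ``coords`` is an (n, 2) array of (row, col) pixel positions.  The
    diameter is the maximum pairwise distance over the pixels' corner
    points (each pixel contributes its 4 corners), computed on the convex
    hull; for tiny or degenerate (collinear) sets the pairwise maximum is
    taken directly.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(coords) == 0:
        raise ValueError("empty pixel set")
    shifts = np.array(
        [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]]
    )
    corners = (coords[:, None, :] + shifts[None, :, :]).reshape(-1, 2)
    corners = np.unique(corners, axis=0)
    pts = corners
    if len(corners) > 8:
        try:
            hull = ConvexHull(corners)
            pts = corners[hull.vertices]
        except QhullError:
            pass  # degenerate hull: fall back to all corner points
    d2max = 0.0
    for (i, p), (j, q) in combinations(enumerate(pts), 2):
        d2 = float(((p - q) ** 2).sum())
        if d2 > d2max:
            d2max = d2
    return float(np.sqrt(d2max)) * calibration.pixel_size


def aspect_ratio(coords: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-fit ellipse of a pixel set.

    Second-order central moments of the pixel centers, regularized by the
    per-pixel variance 1/12 px² on both diagonal terms, give eigenvalues
    λ₁ ≥ λ₂; the ratio is √(λ₁/λ₂) ≥ 1.  Collinear components therefore
    get a finite, large ratio instead of infinity.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(coords) == 0:
        raise ValueError("empty pixel set")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    cov[0, 0] += 1.0 / 12.0
    cov[1, 1] += 1.0 / 12.0
    eigvals = np.linalg.eigvalsh(cov)
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    return float(np.sqrt(lam1 / lam2))


def extract_particles(
    mask: np.ndarray,
    calibration: Calibration,
    config: PipelineConfig,
) -> list[Particle]:
    """Gated particles of a binary mask, ordered by (centroid y, x).

    Components are 8-connected.  The area gate keeps components with
    ``min_particle_area <= area <= max_particle_area`` (bounds inclusive:
    the exclusions are strictly *below* the minimum and strictly *above*
    the maximum).  Holes are not filled.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    px = calibration.pixel_size
    area_per_px = px * px
    particles = []
    for region in measure.regionprops(labels):
        area = region.num_pixels * area_per_px
        # inclusive bounds with relative epsilon so that an area landing
        # exactly on a bound survives float rounding of pixel_size²
        eps = 1e-9 * max(1.0, area)
        if (
            area < config.min_particle_area - eps
            or area > config.max_particle_area + eps
        ):
            continue
        coords = region.coords  # (n, 2) of (row, col)
        cy, cx = region.centroid
        particles.append(
            (
                cy * px,
                cx * px,
                area,
                feret_diameter(coords, calibration),
                aspect_ratio(coords),
            )
        )
    particles.sort(key=lambda t: (t[0], t[1]))
    return [
        Particle(
            particle_id=k,
            area=a,
            feret_diameter=f,
            aspect_ratio=ar,
            centroid=(cx, cy),
        )
        for k, (cy, cx, a, f, ar) in enumerate(particles)
    ]
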