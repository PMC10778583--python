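"""Per-ROI summaries combining tracking and morphology.

The headline statistic is the *fraction of motile mitochondria*: the
number of tracks whose displacement exceeds the motility threshold (the
motility measure) divided by the number of size-gated particles segmented
in the morphology frame (the morphology measure).  The two layers count
different objects — tracked spots and segmented components — so the ratio
can in principle exceed 1; it is then clipped to 1 with a warning.  An ROI
with zero gated particles has an undefined fraction, which is flagged as
missing and excluded from group statistics rather than recorded as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PipelineConfig
from .morphology import Particle
from .tracking import Track, filter_motile, track_displacement, track_mean_speed

__all__ = ["RoiSummary", "motile_fraction", "summarize_roi", "summaries_frame"]

_AGG_METRICS = ("displacement_um", "speed_um_per_s", "area_um2", "feret_um",
                "aspect_ratio")


@dataclass
class RoiSummary:
    """Counts and aggregate statistics of one ROI.

    ``aggregates`` maps each metric name to a dict with ``mean``, ``sd``
    and ``median`` entries; undefined values (empty sample, or SD at
    n = 1) are NaN and are written as empty CSV cells, never as 0.
    """

    roi_id: str
    condition: str
    n_particles: int
    n_tracks: int
    n_motile_tracks: int
    motile_fraction: float  # NaN when undefined
    aggregates: dict[str, dict[str, float]] = field(default_factory=dict)


def motile_fraction(n_motile_tracks: int, n_particles: int) -> float:
    """Motile tracks per gated particle, clipped to 1; NaN for 0 particles."""
    if n_particles < 0 or n_motile_tracks < 0:
        raise ValueError("counts must be non-negative")
    if n_particles == 0:
        warnings.warn(
            "motile fraction undefined for an ROI with 0 particles",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    frac = n_motile_tracks / n_particles
    if frac > 1.0:
        warnings.warn(
            f"motile fraction {frac:.3f} > 1 (more motile tracks than "
            "particles); clipping to 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return frac


def _agg(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"mean": math.nan, "sd": math.nan, "median": math.nan}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
        "median": float(np.median(arr)),
    }


def summarize_roi(
    tracks: Sequence[Track],
    particles: Sequence[Particle],
    config: PipelineConfig,
    roi_id: str,
    condition: str,
    frame_interval: float = 4.0,
) -> RoiSummary:
    """Build the per-ROI metric bundle.

    Displacement statistics run over motile tracks; speed statistics run
    over motile tracks when ``config.speed_on_motile_only`` (the default)
    and over all tracks otherwise; morphology statistics run over the
    gated particles.  The motile fraction uses the denominator selected by
    ``config.motile_fraction_denominator`` (gated particles by default).
    """
    motile = filter_motile(tracks, config.min_track_displacement)
    speed_base = motile if config.speed_on_motile_only else list(tracks)

    if config.motile_fraction_denominator == "tracks":
        denom = len(tracks)
    else:
        denom = len(particles)
    if denom == 0:
        frac = math.nan  # undefined, flagged missing, excluded from group stats
    else:
        frac = motile_fraction(len(motile), denom)

    aggregates = {
        "displacement_um": _agg([track_displacement(t) for t in motile]),
        "speed_um_per_s": _agg(
            [track_mean_speed(t, frame_interval) for t in speed_base]
        ),
        "area_um2": _agg([p.area for p in particles]),
        "feret_um": _agg([p.feret_diameter for p in particles]),
        "aspect_ratio": _agg([p.aspect_ratio for p in particles]),
    }
    return RoiSummary(
        roi_id=roi_id,
        condition=condition,
        n_particles=len(particles),
        n_tracks=len(tracks),
        n_motile_tracks=len(motile),
        motile_fraction=frac,
        aggregates=aggregates,
    )


def summaries_frame(summaries: Sequence[RoiSummary]) -> pd.DataFrame:
    """Flatten ROI summaries to one row per ROI (CSV schema)."""
    rows = []
    for s in summaries:
        row: dict = {
            "roi_id": s.roi_id,
            "condition": s.condition,
            "n_particles": s.n_particles,
            "n_tracks": s.n_tracks,
            "n_motile_tracks": s.n_motile_tracks,
            "motile_fraction": s.motile_fraction,
        }
        for metric in _AGG_METRICS:
            agg = s.aggregates.get(metric, {})
            for stat in ("mean", "sd", "median"):
                row[f"{metric}_{stat}"] = agg.get(stat, math.nan)
        rows.append(row)
    cols = [
        "roi_id", "condition", "n_particles", "n_tracks", "n_motile_tracks",
        "motile_fraction",
    ] + [f"{m}_{s}" for m in _AGG_METRICS for s in ("mean", "sd", "median")]
    return pd.DataFrame(rows, columns=cols)
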