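"""End-to-end orchestration: one ROI, or a batch manifest with statistics.

A single ROI run executes registration → per-frame detection → linking →
motility filtering → first-frame morphometry → ROI summary, and writes the
CSV outputs plus a JSON run manifest.  A batch run processes every row of
a manifest (movie path, roi_id, condition), pools per-observation values
across ROIs per condition, and runs the Kruskal–Wallis/Dunn comparisons on
the preselected condition pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, detection, metrics, morphology, registration, stats, tracking
from .core_io import CalibratedMovie, PipelineConfig, read_movie

__all__ = ["RoiResult", "run_roi", "run_batch", "observation_tables"]

log = logging.getLogger("mitomotion")


@dataclass
class RoiResult:
    roi_id: str
    condition: str
    movie: CalibratedMovie
    drift: registration.DriftTrace | None
    spots: list[detection.Spot]
    tracks: list[tracking.Track]
    particles: list[morphology.Particle]
    summary: metrics.RoiSummary
    output_paths: dict[str, Path] = field(default_factory=dict)


def run_roi(
    movie: CalibratedMovie | str | Path,
    config: PipelineConfig | None = None,
    roi_id: str = "roi",
    condition: str = "unknown",
    out_dir: str | Path | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    register: bool = True,
) -> RoiResult:
    """Run the full analysis on one movie.

    A single-frame movie yields morphology outputs only; tracking is
    skipped with a logged notice.  When ``out_dir`` is given, all CSV
    tables, the drift trace and the run manifest are written there.
    """
    config = config or PipelineConfig()
    if not isinstance(movie, CalibratedMovie):
        movie = read_movie(movie, pixel_size=pixel_size,
                           frame_interval=frame_interval)
    cal = movie.calibration
    log.info("[%s] %d frames, %.3g µm/px, %.3g s/frame", roi_id,
             movie.n_frames, cal.pixel_size, cal.frame_interval)

    drift = None
    corrected = movie
    if register and movie.n_frames > 1:
        drift = registration.estimate_drift(movie)
        corrected = registration.apply_correction(movie, drift)
        log.info("[%s] max |drift| %.2f px", roi_id,
                 float(np.abs(drift.offsets).max()))

    spots: list[detection.Spot] = []
    tracks: list[tracking.Track] = []
    if movie.n_frames > 1:
        spots_by_frame = [
            detection.detect_spots(corrected.frame(t), config, cal, frame_index=t)
            for t in range(corrected.n_frames)
        ]
        spots = [s for frame_spots in spots_by_frame for s in frame_spots]
        log.info("[%s] %d spots (%.1f/frame)", roi_id, len(spots),
                 len(spots) / corrected.n_frames)
        tracks = tracking.build_tracks(spots_by_frame, config)
        log.info("[%s] %d tracks, %d motile", roi_id, len(tracks),
                 len(tracking.filter_motile(tracks, config.min_track_displacement)))
    else:
        log.info("[%s] single frame: tracking skipped, morphology only", roi_id)

    frame0 = morphology.select_morphology_frame(corrected, config)
    mask = morphology.segment(frame0, config.threshold_method)
    particles = morphology.extract_particles(mask, cal, config)
    log.info("[%s] %d gated particles", roi_id, len(particles))

    summary = metrics.summarize_roi(
        tracks, particles, config, roi_id, condition,
        frame_interval=cal.frame_interval,
    )

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        paths = core_io.write_tables(
            spots, tracks, particles, metrics.summaries_frame([summary]),
            out_dir, config=config, frame_interval=cal.frame_interval,
        )
        if drift is not None:
            paths["drift"] = registration.write_drift(drift, out_dir / "drift.csv")
        paths["manifest"] = core_io.write_run_manifest(
            out_dir, config, inputs={"roi_id": roi_id, "condition": condition}
        )
    return RoiResult(
        roi_id=roi_id, condition=condition, movie=movie, drift=drift,
        spots=spots, tracks=tracks, particles=particles, summary=summary,
        output_paths=paths,
    )


def observation_tables(results: list[RoiResult],
                       config: PipelineConfig) -> pd.DataFrame:
    """Long-format per-observation table for the group statistics.

    Per-track metrics (displacement over motile tracks; speed over motile
    or all tracks per config) and per-particle metrics enter with one row
    per object; the motile fraction enters with one row per ROI.
    """
    rows = []
    for r in results:
        cal = r.movie.calibration
        motile = tracking.filter_motile(r.tracks, config.min_track_displacement)
        speed_base = motile if config.speed_on_motile_only else r.tracks
        for t in motile:
            rows.append(
                {"metric": "displacement_um", "condition": r.condition,
                 "roi_id": r.roi_id,
                 "value": tracking.track_displacement(t)}
            )
        for t in speed_base:
            rows.append(
                {"metric": "speed_um_per_s", "condition": r.condition,
                 "roi_id": r.roi_id,
                 "value": tracking.track_mean_speed(t, cal.frame_interval)}
            )
        for p in r.particles:
            rows.append({"metric": "area_um2", "condition": r.condition,
                         "roi_id": r.roi_id, "value": p.area})
            rows.append({"metric": "feret_um", "condition": r.condition,
                         "roi_id": r.roi_id, "value": p.feret_diameter})
            rows.append({"metric": "aspect_ratio", "condition": r.condition,
                         "roi_id": r.roi_id, "value": p.aspect_ratio})
        rows.append(
            {"metric": "motile_fraction", "condition": r.condition,
             "roi_id": r.roi_id, "value": r.summary.motile_fraction}
        )
    return pd.DataFrame(rows, columns=["metric", "condition", "roi_id", "value"])


def run_batch(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    pairs: list[tuple[str, str]] | None = None,
    out_dir: str | Path | None = None,
    skip_failures: bool = False,
) -> dict:
    """Run every ROI of a manifest and compare conditions.

    ``manifest`` needs columns ``path``, ``roi_id``, ``condition``.  With
    fewer than two conditions the summary is still written but statistics
    are skipped with a notice.  A failing ROI aborts the batch unless
    ``skip_failures`` is set.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"path", "roi_id", "condition"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if manifest["roi_id"].duplicated().any():
        raise ValueError("manifest roi_ids must be unique")

    results: list[RoiResult] = []
    for _, row in manifest.iterrows():
        roi_dir = Path(out_dir) / str(row["roi_id"]) if out_dir else None
        try:
            results.append(
                run_roi(
                    row["path"], config, roi_id=str(row["roi_id"]),
                    condition=str(row["condition"]), out_dir=roi_dir,
                )
            )
        except Exception:
            if skip_failures:
                log.exception("[%s] ROI failed; skipping", row["roi_id"])
                continue
            raise RuntimeError(
                f"ROI {row['roi_id']!r} ({row['path']}) failed"
            ) from None

    summaries = metrics.summaries_frame([r.summary for r in results])
    observations = observation_tables(results, config)

    comparisons = []
    conditions = sorted({r.condition for r in results})
    if len(conditions) < 2:
        log.info("only %d condition(s): statistics skipped", len(conditions))
    else:
        if pairs is None:
            raise ValueError("pairs must be given for multi-condition batches")
        for metric in observations["metric"].unique():
            obs = observations[observations["metric"] == metric].dropna(
                subset=["value"]
            )
            present = set(obs["condition"])
            if any(g not in present for pair in pairs for g in pair):
                log.info("metric %s: missing condition data, skipped", metric)
                continue
            comparisons.append(stats.compare_conditions(obs, metric, pairs))
    stats_df = stats.comparisons_frame(comparisons)

    paths = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out_dir / "roi_summary.csv", index=False,
                         lineterminator="\n")
        observations.to_csv(out_dir / "observations.csv", index=False,
                            lineterminator="\n")
        stats_df.to_csv(out_dir / "stats.csv", index=False, lineterminator="\n")
        paths = {
            "roi_summary": out_dir / "roi_summary.csv",
            "observations": out_dir / "observations.csv",
            "stats": out_dir / "stats.csv",
        }
    return {
        "results": results,
        "summaries": summaries,
        "observations": observations,
        "comparisons": comparisons,
        "stats": stats_df,
        "paths": paths,
    }
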