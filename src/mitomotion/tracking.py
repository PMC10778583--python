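"""Frame-to-frame spot linking and per-track motion features.

Linking follows the LAP (linear assignment problem) frame-to-frame stage:
spots of frame *t* are matched one-to-one to spots of frame *t+1* so that
the total squared Euclidean distance is minimal, using only candidate
pairs within the hard distance cutoff.  Leaving a spot unmatched carries
the alternative cost ``cutoff²``, which makes every feasible link
profitable: the optimum is the maximum-cardinality feasible matching of
minimal squared cost.  The assignment is solved exactly (Hungarian
algorithm), so small instances can be checked against exhaustive
enumeration.

Gap closing is disabled: a spot unmatched in the next frame terminates its
track, and a particle reappearing later starts a new track.  Tracks need
at least two spots; displacement (straight-line start-to-end distance) and
mean speed (path length / duration) are then well defined.  Motility is a
strict displacement criterion: a track is motile iff its displacement
exceeds the configured threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_io import PipelineConfig
from .detection import Spot

__all__ = [
    "Track",
    "link_frame_pair",
    "build_tracks",
    "track_displacement",
    "track_mean_speed",
    "filter_motile",
    "linking_cost",
]

_BIG = 1e12  # forbidden-assignment cost; no feasible pair comes close


@dataclass
class Track:
    """An ordered chain of spots on strictly consecutive frames."""

    track_id: int
    spots: list[Spot]

    def __post_init__(self) -> None:
        if len(self.spots) < 2:
            raise ValueError("a track needs at least 2 spots")
        frames = [s.frame for s in self.spots]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")

    def positions(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    @property
    def first_frame(self) -> int:
        return self.spots[0].frame

    @property
    def last_frame(self) -> int:
        return self.spots[-1].frame


def link_frame_pair(
    spots_a: Sequence[Spot],
    spots_b: Sequence[Spot],
    max_link_distance: float,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two consecutive frames.

    Returns index pairs ``(i, j)`` meaning ``spots_a[i]`` links to
    ``spots_b[j]``.  Only pairs within ``max_link_distance`` (µm) are
    eligible; unmatched spots are allowed at alternative cost
    ``max_link_distance²`` each.  Empty inputs yield an empty matching.
    """
    n, m = len(spots_a), len(spots_b)
    if n == 0 or m == 0:
        return []
    pa = np.array([[s.x, s.y] for s in spots_a])
    pb = np.array([[s.x, s.y] for s in spots_b])
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    cutoff2 = max_link_distance**2
    alt = cutoff2

    # padded square LAP: top-left real costs, diagonal dummies for
    # unmatched spots, zero block for dummy-dummy
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, :m] = np.where(d2 <= cutoff2, d2, _BIG)
    cost[:n, m:] = _BIG
    cost[:n, m:][np.arange(n), np.arange(n)] = alt
    cost[n:, :m] = _BIG
    cost[n:, :m][np.arange(m), np.arange(m)] = alt
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= cutoff2
    ]


def linking_cost(
    spots_a: Sequence[Spot],
    spots_b: Sequence[Spot],
    matches: Sequence[tuple[int, int]],
    max_link_distance: float,
) -> float:
    """Total LAP objective of a matching: Σ d² + cutoff² per unmatched spot."""
    pa = np.array([[s.x, s.y] for s in spots_a]).reshape(-1, 2)
    pb = np.array([[s.x, s.y] for s in spots_b]).reshape(-1, 2)
    total = sum(((pa[i] - pb[j]) ** 2).sum() for i, j in matches)
    n_unmatched = (len(spots_a) - len(matches)) + (len(spots_b) - len(matches))
    return float(total + max_link_distance**2 * n_unmatched)


def build_tracks(
    spots_by_frame: Sequence[Sequence[Spot]],
    config: PipelineConfig,
) -> list[Track]:
    """Chain pairwise matches into tracks; no gap closing.

    ``spots_by_frame[t]`` holds the spots of frame ``t``.  A spot with no
    match in the next frame terminates its chain; chains of length 1 are
    not emitted.  Each spot belongs to at most one track.
    """
    if config.gap_closing:
        raise NotImplementedError("gap closing is not supported")
    chains: list[list[Spot]] = []
    # open_chains[i] = chain index currently ending at spots_by_frame[t][i]
    open_chains: dict[int, int] = {}
    for t in range(len(spots_by_frame) - 1):
        matches = link_frame_pair(
            spots_by_frame[t], spots_by_frame[t + 1], config.max_link_distance
        )
        next_open: dict[int, int] = {}
        for i, j in matches:
            if i in open_chains:
                ci = open_chains[i]
                chains[ci].append(spots_by_frame[t + 1][j])
            else:
                chains.append([spots_by_frame[t][i], spots_by_frame[t + 1][j]])
                ci = len(chains) - 1
            next_open[j] = ci
        open_chains = next_open
    return [
        Track(track_id=k, spots=chain)
        for k, chain in enumerate(c for c in chains if len(c) >= 2)
    ]


def track_displacement(track: Track) -> float:
    """Straight-line distance between first and last spot, µm."""
    pos = track.positions()
    return float(np.linalg.norm(pos[-1] - pos[0]))


def track_path_length(track: Track) -> float:
    """Total traveled path length, µm."""
    pos = track.positions()
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def track_mean_speed(track: Track, frame_interval: float) -> float:
    """Path length divided by track duration, µm/s."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n_steps = len(track.spots) - 1
    return track_path_length(track) / (n_steps * frame_interval)


def filter_motile(
    tracks: Sequence[Track], min_track_displacement: float
) -> list[Track]:
    """Tracks with displacement strictly above the threshold, order kept."""
    return [t for t in tracks if track_displacement(t) > min_track_displacement]
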