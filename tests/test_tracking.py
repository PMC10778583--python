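from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomotion import (
    PipelineConfig,
    SceneConfig,
    build_tracks,
    filter_motile,
    link_frame_pair,
    simulate_movie,
    track_displacement,
    track_mean_speed,
)
from mitomotion.detection import Spot
from mitomotion.tracking import Track, linking_cost, track_path_length


def _spots(frame, positions):
    return [Spot(frame, float(x), float(y), 1.0) for x, y in positions]


def brute_force_cost(spots_a, spots_b, cutoff):
    """Minimum LAP objective by exhaustive enumeration of matchings."""
    pa = np.array([[s.x, s.y] for s in spots_a]).reshape(-1, 2)
    pb = np.array([[s.x, s.y] for s in spots_b]).reshape(-1, 2)
    n, m = len(pa), len(pb)
    best = cutoff**2 * (n + m)  # empty matching
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in permutations(range(m), k):
                cost = 0.0
                feasible = True
                for i, j in zip(rows, cols):
                    d2 = float(((pa[i] - pb[j]) ** 2).sum())
                    if d2 > cutoff**2:
                        feasible = False
                        break
                    cost += d2
                if feasible:
                    cost += cutoff**2 * ((n - k) + (m - k))
                    best = min(best, cost)
    return best


class TestLinkFramePair:
    def test_empty_input_gives_empty_matching(self):
        assert link_frame_pair([], _spots(1, [(0, 0)]), 2.0) == []
        assert link_frame_pair(_spots(0, [(0, 0)]), [], 2.0) == []

    def test_distance_cutoff_is_hard(self):
        a = _spots(0, [(0.0, 0.0)])
        assert link_frame_pair(a, _spots(1, [(0.0, 1.9)]), 2.0) == [(0, 0)]
        assert link_frame_pair(a, _spots(1, [(0.0, 2.1)]), 2.0) == []

    def test_matching_is_one_to_one(self):
        a = _spots(0, [(0, 0), (1, 0)])
        b = _spots(1, [(0.5, 0)])
        matches = link_frame_pair(a, b, 2.0)
        assert len(matches) == 1
        assert len({j for _, j in matches}) == len(matches)

    @pytest.mark.parametrize("seed", range(20))
    def test_cost_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(0, 7, size=2)
        a = _spots(0, rng.uniform(0, 6, size=(n, 2)))
        b = _spots(1, rng.uniform(0, 6, size=(m, 2)))
        matches = link_frame_pair(a, b, 2.0)
        assert linking_cost(a, b, matches, 2.0) == pytest.approx(
            brute_force_cost(a, b, 2.0), abs=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 5), st.integers(0, 5), st.integers(0, 10_000))
    def test_cost_optimality_property(self, n, m, seed):
        rng = np.random.default_rng(seed)
        a = _spots(0, rng.uniform(0, 5, size=(n, 2)))
        b = _spots(1, rng.uniform(0, 5, size=(m, 2)))
        matches = link_frame_pair(a, b, 2.0)
        assert linking_cost(a, b, matches, 2.0) <= brute_force_cost(a, b, 2.0) + 1e-9


class TestBuildTracks:
    def test_unambiguous_chain_gives_one_track(self, config):
        frames = [_spots(t, [(0.1 * t, 0.0)]) for t in range(31)]
        tracks = build_tracks(frames, config)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 31

    def test_gap_splits_into_two_tracks(self, config):
        # present frames 0-2, absent 3, present 4-7: no gap closing
        frames = []
        for t in range(8):
            frames.append([] if t == 3 else _spots(t, [(0.0, 0.0)]))
        tracks = build_tracks(frames, config)
        assert sorted(len(t.spots) for t in tracks) == [3, 4]

    def test_singletons_are_not_tracks(self, config):
        frames = [_spots(0, [(0, 0)]), _spots(1, [(10.0, 10.0)])]
        assert build_tracks(frames, config) == []

    def test_spot_conservation_per_frame(self, config):
        rng = np.random.default_rng(0)
        frames = [
            _spots(t, rng.uniform(0, 20, size=(6, 2))) for t in range(5)
        ]
        tracks = build_tracks(frames, config)
        used = [0] * 5
        for tr in tracks:
            for s in tr.spots:
                used[s.frame] += 1
        for t in range(5):
            assert used[t] <= len(frames[t])

    def test_simulator_tracks_fully_recovered(self):
        scene = SceneConfig(seed=21, n_mitochondria=30)
        movie, truth = simulate_movie(scene)
        cfg = scene.pipeline_config()
        from mitomotion import detect_spots

        spots_by_frame = [
            detect_spots(movie.frames[t], cfg, scene.calibration, t)
            for t in range(movie.n_frames)
        ]
        tracks = build_tracks(spots_by_frame, cfg)
        assert len(tracks) == 30
        assert all(len(t.spots) == 31 for t in tracks)


class TestTrackFeatures:
    def test_displacement_345_triangle(self):
        t = Track(0, [Spot(0, 0.0, 0.0, 1), Spot(1, 3.0, 4.0, 1)])
        assert track_displacement(t) == pytest.approx(5.0)

    def test_closed_loop_displacement_zero(self):
        t = Track(
            0,
            [
                Spot(0, 0.0, 0.0, 1),
                Spot(1, 1.0, 0.0, 1),
                Spot(2, 1.0, 1.0, 1),
                Spot(3, 0.0, 0.0, 1),
            ],
        )
        assert track_displacement(t) == pytest.approx(0.0)

    def test_straight_path_displacement(self):
        spots = [Spot(t, 0.1 * t, 0.0, 1) for t in range(31)]
        assert track_displacement(Track(0, spots)) == pytest.approx(3.0)

    def test_mean_speed_examples(self):
        t = Track(
            0, [Spot(0, 0.0, 0.0, 1), Spot(1, 1.0, 0.0, 1), Spot(2, 2.0, 0.0, 1)]
        )
        assert track_mean_speed(t, 4.0) == pytest.approx(0.25)
        stationary = Track(0, [Spot(0, 1.0, 1.0, 1), Spot(1, 1.0, 1.0, 1)])
        assert track_mean_speed(stationary, 4.0) == 0.0

    def test_zigzag_mean_speed(self):
        # total path 6 µm over 10 steps of 4 s -> 0.15 µm/s
        spots = [Spot(0, 0.0, 0.0, 1)]
        x = 0.0
        for i in range(10):
            x += 0.6 if i % 2 == 0 else -0.6
            spots.append(Spot(i + 1, x, 0.0, 1))
        t = Track(0, spots)
        assert track_path_length(t) == pytest.approx(6.0)
        assert track_mean_speed(t, 4.0) == pytest.approx(0.15)

    def test_displacement_never_exceeds_path_length(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(2, 12)
            pts = rng.uniform(0, 10, size=(n, 2))
            spots = [Spot(t, *pts[t], 1.0) for t in range(n)]
            tr = Track(0, spots)
            assert track_displacement(tr) <= track_path_length(tr) + 1e-12

    def test_track_invariants_enforced(self):
        with pytest.raises(ValueError):
            Track(0, [Spot(0, 0.0, 0.0, 1)])
        with pytest.raises(ValueError):
            Track(0, [Spot(0, 0.0, 0.0, 1), Spot(2, 0.0, 0.0, 1)])


class TestFilterMotile:
    def test_strictly_above_threshold(self):
        def track_with_displacement(d):
            return Track(0, [Spot(0, 0.0, 0.0, 1), Spot(1, d, 0.0, 1)])

        tracks = [track_with_displacement(d) for d in (0.5, 1.5, 1.6, 3.0)]
        kept = filter_motile(tracks, 1.5)
        assert [track_displacement(t) for t in kept] == pytest.approx([1.6, 3.0])

    def test_empty_input(self):
        assert filter_motile([], 1.5) == []

    def test_zero_threshold_keeps_positive_displacement(self):
        moving = Track(0, [Spot(0, 0.0, 0.0, 1), Spot(1, 0.1, 0.0, 1)])
        still = Track(1, [Spot(0, 0.0, 0.0, 1), Spot(1, 0.0, 0.0, 1)])
        assert filter_motile([moving, still], 0.0) == [moving]
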