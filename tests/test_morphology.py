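import math
from itertools import combinations

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from mitomotion import (
    CalibratedMovie,
    Calibration,
    PipelineConfig,
    aspect_ratio,
    extract_particles,
    feret_diameter,
    segment,
    select_morphology_frame,
    simulate_movie,
)
from mitomotion.simulator import SceneConfig


def brute_force_feret(coords, pixel_size):
    """Max pairwise distance over all pixel corner points, µm."""
    shifts = [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)]
    pts = {(r + dr, c + dc) for r, c in map(tuple, coords) for dr, dc in shifts}
    return max(
        math.dist(p, q) for p, q in combinations(pts, 2)
    ) * pixel_size


class TestSelectMorphologyFrame:
    def test_default_is_first_frame(self, calibration, config):
        frames = np.arange(31 * 4 * 4, dtype=float).reshape(31, 4, 4)
        movie = CalibratedMovie(frames, calibration)
        np.testing.assert_array_equal(
            select_morphology_frame(movie, config), frames[0]
        )

    def test_configured_index(self, calibration):
        frames = np.arange(10 * 4 * 4, dtype=float).reshape(10, 4, 4)
        movie = CalibratedMovie(frames, calibration)
        cfg = PipelineConfig(morphology_frame_index=5)
        np.testing.assert_array_equal(
            select_morphology_frame(movie, cfg), frames[5]
        )

    def test_one_frame_movie(self, calibration, config):
        movie = CalibratedMovie(np.zeros((1, 4, 4)), calibration)
        np.testing.assert_array_equal(
            select_morphology_frame(movie, config), movie.frames[0]
        )

    def test_out_of_range_rejected(self, calibration):
        movie = CalibratedMovie(np.zeros((2, 4, 4)), calibration)
        with pytest.raises(IndexError):
            select_morphology_frame(
                movie, PipelineConfig(morphology_frame_index=5)
            )


class TestSegment:
    def _two_level(self):
        img = np.full((32, 32), 10.0)
        img[5:10, 5:12] = 100.0
        img[20:25, 18:22] = 100.0
        return img

    def test_fixed_threshold_recovers_exact_blobs(self):
        img = self._two_level()
        np.testing.assert_array_equal(segment(img, 50.0), img >= 50.0)

    def test_otsu_matches_fixed_on_bimodal_image(self):
        img = self._two_level()
        np.testing.assert_array_equal(segment(img, "otsu"), segment(img, 50.0))

    def test_all_zero_frame_fixed_threshold(self):
        assert not segment(np.zeros((8, 8)), 1.0).any()

    def test_constant_frame_otsu_instructs_fixed_value(self):
        with pytest.raises(ValueError, match="fixed"):
            segment(np.full((8, 8), 7.0), "otsu")


class TestExtractParticles:
    def test_area_gate_bounds_are_inclusive(self, calibration, config):
        # pixel counts 2, 5, 125, 130 at 0.04 µm²/px give areas
        # 0.08 (below min), 0.2 (= min), 5.0 (= max), 5.2 (above max)
        mask = np.zeros((120, 120), dtype=bool)

        def put(r0, c0, n_px):
            placed = 0
            width = int(np.ceil(np.sqrt(n_px)))
            for dr in range(width + 2):
                for dc in range(width):
                    if placed < n_px:
                        mask[r0 + dr, c0 + dc] = True
                        placed += 1

        for i, n_px in enumerate([2, 5, 125, 130]):
            put(5 + 25 * i, 10, n_px)
        particles = extract_particles(mask, calibration, config)
        assert sorted(p.area for p in particles) == pytest.approx([0.2, 5.0])

    def test_square_area_counts_pixels(self, calibration, config):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:8, 3:8] = True  # 25 px * 0.04 = 1.0 µm²
        (p,) = extract_particles(mask, calibration, config)
        assert p.area == pytest.approx(1.0)

    def test_diagonal_pixels_are_one_component(self, calibration):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = mask[4, 4] = True
        cfg = PipelineConfig(min_particle_area=0.04, max_particle_area=5.0)
        assert len(extract_particles(mask, calibration, cfg)) == 1

    def test_empty_mask(self, calibration, config):
        assert extract_particles(np.zeros((8, 8), bool), calibration, config) == []

    def test_widening_gate_never_drops_particles(self, calibration):
        rng = np.random.default_rng(3)
        mask = rng.random((80, 80)) > 0.7
        narrow = PipelineConfig(min_particle_area=0.2, max_particle_area=2.0)
        wide = PipelineConfig(min_particle_area=0.1, max_particle_area=5.0)
        kept_narrow = {
            p.centroid for p in extract_particles(mask, calibration, narrow)
        }
        kept_wide = {
            p.centroid for p in extract_particles(mask, calibration, wide)
        }
        assert kept_narrow <= kept_wide

    def test_count_conservation(self, calibration, config):
        from skimage import measure

        rng = np.random.default_rng(4)
        mask = rng.random((60, 60)) > 0.8
        n_components = measure.label(mask, connectivity=2).max()
        retained = len(extract_particles(mask, calibration, config))
        excluded = n_components - retained
        assert retained + excluded == n_components
        assert excluded >= 0


class TestFeretDiameter:
    def test_single_pixel_is_its_diagonal(self, calibration):
        assert feret_diameter(np.array([[3, 3]]), calibration) == pytest.approx(
            0.2 * math.sqrt(2)
        )

    def test_rectangle_close_to_diagonal(self, calibration):
        coords = np.argwhere(np.ones((5, 20), dtype=bool))
        expected = math.hypot(20, 5) * 0.2
        assert feret_diameter(coords, calibration) == pytest.approx(
            expected, abs=0.2 * math.sqrt(2)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_components(self, seed, calibration):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 40)
        coords = np.unique(rng.integers(0, 12, size=(n, 2)), axis=0)
        assert feret_diameter(coords, calibration) == pytest.approx(
            brute_force_feret(coords, 0.2), abs=1e-9
        )


class TestAspectRatio:
    def test_disk_is_circular(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = np.argwhere((yy - 20) ** 2 + (xx - 20) ** 2 <= 100)
        assert aspect_ratio(disk) == pytest.approx(1.0, abs=0.05)

    def test_rectangle_ratio_is_side_ratio(self):
        coords = np.argwhere(np.ones((5, 20), dtype=bool))
        assert aspect_ratio(coords) == pytest.approx(4.0, abs=0.15)

    def test_line_is_finite_and_large(self):
        line = np.array([[0, i] for i in range(10)])
        ar = aspect_ratio(line)
        assert math.isfinite(ar)
        assert ar >= 5.0


class TestRotatedEllipse:
    @pytest.mark.parametrize("deg", [0, 30, 45, 75, 110, 150])
    def test_shape_measures_rotation_tolerant(self, deg, calibration, config):
        # 3 µm × 1 µm ellipse: area π·1.5·0.5, AR 3, Feret 3 µm
        img = np.zeros((120, 120))
        rr, cc = draw_ellipse(
            60, 60, 1.5 / 0.2, 0.5 / 0.2, rotation=np.deg2rad(deg)
        )
        img[rr, cc] = 100.0
        (p,) = extract_particles(segment(img, 50.0), calibration, config)
        assert p.area == pytest.approx(math.pi * 0.75, rel=0.10)
        assert p.aspect_ratio == pytest.approx(3.0, rel=0.10)
        assert p.feret_diameter == pytest.approx(3.0, rel=0.10)


class TestAgainstSimulatorTruth:
    def test_recovered_shapes_match_analytic_truth(self):
        scene = SceneConfig(seed=13, n_mitochondria=60, snr=20.0)
        movie, truth = simulate_movie(scene)
        cfg = scene.pipeline_config()
        particles = extract_particles(
            segment(movie.frames[0], cfg.threshold_method),
            scene.calibration,
            cfg,
        )
        assert len(particles) == 60
        mean_area = np.mean([p.area for p in particles])
        mean_feret = np.mean([p.feret_diameter for p in particles])
        truth_blobs = truth["blobs"]
        assert mean_area == pytest.approx(truth_blobs["area_um2"].mean(), rel=0.15)
        assert mean_feret == pytest.approx(truth_blobs["feret_um"].mean(), rel=0.15)
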