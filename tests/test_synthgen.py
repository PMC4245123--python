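"""Synthetic population, sedimentation, rendering, and track generation."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from vesiclepop.errors import ParameterError
from vesiclepop.synthgen import (
    MotionModel,
    PopulationParams,
    RenderParams,
    generate_track,
    render_frame,
    sample_population,
    simulate_sedimentation,
    visible_at,
)


def shoelace_ipq(polygon):
    """Independent IPQ oracle: shoelace area over squared segment-sum perimeter."""
    r, c = polygon[:, 0], polygon[:, 1]
    area = 0.5 * abs(np.sum(c[:-1] * r[1:] - c[1:] * r[:-1]))
    d = np.diff(polygon, axis=0)
    perim = np.sum(np.hypot(d[:, 0], d[:, 1]))
    return 4.0 * np.pi * area / perim**2


class TestSamplePopulation:
    def test_empty_population(self):
        assert sample_population(PopulationParams(n_vesicles=0)) == []

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_diameters_within_bounds(self, seed):
        pop = sample_population(PopulationParams(n_vesicles=200, seed=seed))
        d = np.array([v.diameter_um for v in pop])
        assert d.min() >= 1.0 and d.max() <= 50.0

    def test_mean_ipq_matches_target(self):
        pop = sample_population(PopulationParams(n_vesicles=500, target_mean_ipq=0.95, seed=1))
        ipqs = [shoelace_ipq(v.contour_um) for v in pop]
        assert 0.94 <= np.mean(ipqs) <= 0.96
        # stored true_ipq agrees with the oracle recomputation
        assert np.allclose(ipqs, [v.true_ipq for v in pop], atol=1e-9)

    def test_contour_area_consistent_with_diameter(self):
        pop = sample_population(PopulationParams(n_vesicles=50, seed=2))
        for v in pop:
            poly = v.contour_um
            area = 0.5 * abs(np.sum(poly[:-1, 1] * poly[1:, 0] - poly[1:, 1] * poly[:-1, 0]))
            assert area == pytest.approx(np.pi * (v.diameter_um / 2) ** 2, rel=0.01)
            assert np.allclose(poly[0], poly[-1])
            assert 0 < v.true_ipq <= 1.0 + 1e-9

    def test_contours_are_simple(self):
        from shapely.geometry import Polygon

        pop = sample_population(PopulationParams(n_vesicles=30, target_mean_ipq=0.9, seed=3))
        assert all(Polygon(v.contour_um).is_valid for v in pop)

    def test_determinism(self):
        a = sample_population(PopulationParams(n_vesicles=40, seed=9))
        b = sample_population(PopulationParams(n_vesicles=40, seed=9))
        for va, vb in zip(a, b):
            assert va.diameter_um == vb.diameter_um
            assert va.settled_at_min == vb.settled_at_min
            assert np.array_equal(va.contour_um, vb.contour_um)

    def test_size_law_matches_truncated_lognormal_oracle(self):
        """Log-diameter moments match direct rejection sampling within 2%."""
        mu, sigma = np.log(6.5), 0.6
        pop = sample_population(PopulationParams(n_vesicles=10_000, seed=4))
        logs = np.log([v.diameter_um for v in pop])
        # oracle: rejection-sample the same truncated lognormal
        rng = np.random.default_rng(123)
        draws = rng.lognormal(mu, sigma, size=200_000)
        draws = draws[(draws >= 1.0) & (draws <= 50.0)]
        oracle = np.log(draws)
        assert logs.mean() == pytest.approx(oracle.mean(), rel=0.02)
        assert logs.std() == pytest.approx(oracle.std(), rel=0.02)

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ParameterError, match="diam_min"):
            PopulationParams(diam_min=5.0, diam_max=2.0).validate()
        with pytest.raises(ParameterError, match="target_mean_ipq"):
            PopulationParams(target_mean_ipq=1.5).validate()
        with pytest.raises(ParameterError, match="n_vesicles"):
            PopulationParams(n_vesicles=-1).validate()


class TestSedimentation:
    def test_nothing_settles_instantly(self):
        assert simulate_sedimentation(10.0, 0.0) == 0.0

    def test_monotone_in_diameter_and_time(self):
        times = np.linspace(0, 120, 25)
        p_small = simulate_sedimentation(5.0, times)
        p_large = simulate_sedimentation(20.0, times)
        assert np.all(p_large >= p_small)
        assert np.all(np.diff(p_small) >= 0) and np.all(np.diff(p_large) >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            simulate_sedimentation(10.0, -1.0)
        with pytest.raises(ParameterError):
            simulate_sedimentation(-1.0, 10.0)

    def test_visible_count_ratio_60_vs_30_min(self):
        """Monte-Carlo over a default-size population: late settling slows down."""
        pop = sample_population(PopulationParams(n_vesicles=2000, seed=6))
        d = np.array([v.diameter_um for v in pop])
        expected_30 = simulate_sedimentation(d, 30.0).sum()
        expected_60 = simulate_sedimentation(d, 60.0).sum()
        assert 1.1 <= expected_60 / expected_30 <= 1.6

    def test_visible_at_is_monotone_in_time(self):
        pop = sample_population(PopulationParams(n_vesicles=300, seed=7))
        counts = [len(visible_at(pop, t)) for t in (0, 3, 10, 30, 60, 120)]
        assert counts == sorted(counts)

    def test_larger_vesicles_settle_first_on_average(self):
        pop = sample_population(PopulationParams(n_vesicles=2000, seed=8))
        d = np.array([v.diameter_um for v in pop])
        t = np.array([v.settled_at_min for v in pop])
        large, small = d > np.median(d), d <= np.median(d)
        assert t[large].mean() < t[small].mean()


class TestRenderFrame:
    def test_empty_scene_is_flat_background(self):
        params = RenderParams(frame_shape=(64, 64), noise_sigma=0.0)
        out = render_frame([], (0.0, 0.0), params)
        assert np.all(out.image == int(params.background_level))
        assert out.mask.max() == 0

    def test_ring_outer_diameter_matches_calibration(self):
        """A 10 um vesicle at 0.25 um/px spans ~40 px in the mask."""
        pop = sample_population(
            PopulationParams(n_vesicles=1, target_mean_ipq=1.0, chamber_um=(50.0, 50.0),
                             diam_min=9.99, diam_max=10.01, seed=0)
        )
        out = render_frame(pop, (0.0, 0.0), RenderParams(frame_shape=(200, 200), noise_sigma=0.0))
        rows = np.any(out.mask > 0, axis=1).nonzero()[0]
        assert rows.max() - rows.min() + 1 == pytest.approx(40, abs=2)

    def test_mask_labels_only_fully_inside_vesicles(self, small_population, rendered_scene):
        reach = {
            v.id: v.max_radius_um / 0.25 + 3 * 1.5 for v in small_population
        }
        inside = [
            v.id
            for v in small_population
            if v.center_rc_um[0] / 0.25 - reach[v.id] >= 0
            and v.center_rc_um[1] / 0.25 - reach[v.id] >= 0
            and v.center_rc_um[0] / 0.25 + reach[v.id] <= 800
            and v.center_rc_um[1] / 0.25 + reach[v.id] <= 762
        ]
        assert rendered_scene.mask.max() == len(inside)
        assert sorted(rendered_scene.vesicle_ids) == sorted(inside)

    def test_intensities_are_8bit(self, rendered_scene):
        assert rendered_scene.image.dtype == np.uint8

    def test_invalid_render_params(self):
        with pytest.raises(ParameterError, match="ring_width_px"):
            RenderParams(ring_width_px=0.5).validate()
        with pytest.raises(ParameterError, match="ring_contrast"):
            RenderParams(background_level=50, ring_contrast=90).validate()


class TestGenerateTrack:
    def test_zero_motion_keeps_offsets_zero(self, small_population):
        params = RenderParams(frame_shape=(128, 128), seed=1, noise_sigma=0.0)
        motion = MotionModel(step_mean_px=0.0, step_jitter_px=0.0, transverse_jitter_px=0.0)
        track, offsets = generate_track(small_population, motion, 5, params)
        assert np.all(offsets == 0)
        for f in track.frames[1:]:
            assert np.array_equal(f, track.frames[0])

    def test_track_extent_matches_summed_displacements(self, small_population):
        params = RenderParams(frame_shape=(128, 128), seed=2)
        track, offsets = generate_track(small_population, MotionModel(), 100, params)
        assert len(track.frames) == 100
        # mosaic extent would be frame height + net displacement
        assert offsets[-1, 0] == pytest.approx(2.0 * 99, abs=3 * 0.5 * np.sqrt(99))

    def test_fixed_seed_bit_identical(self, small_population):
        params = RenderParams(frame_shape=(96, 96), seed=3)
        t1, o1 = generate_track(small_population, MotionModel(), 6, params)
        t2, o2 = generate_track(small_population, MotionModel(), 6, params)
        assert np.array_equal(o1, o2)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a, b)

    def test_insufficient_overlap_rejected(self, small_population):
        params = RenderParams(frame_shape=(64, 64))
        with pytest.raises(ParameterError, match="overlap"):
            generate_track(small_population, MotionModel(step_mean_px=60.0), 5, params)

    def test_too_few_frames_rejected(self, small_population):
        with pytest.raises(ParameterError, match="n_frames"):
            generate_track(small_population, MotionModel(), 1, RenderParams())
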