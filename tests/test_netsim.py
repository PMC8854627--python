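"""Simulator: network geometry, rasterisation, binning, microscope emulation."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk

from cortexmesh import (
    FilamentNetwork,
    Segment,
    SimulationParams,
    bin_image,
    emulate_microscope,
    make_density_series,
    rasterize,
    simulate_network,
    simulate_pair,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_seed_filaments": -1},
        {"branch_angle_deg": 0.0},
        {"branch_angle_deg": 95.0},
        {"field_size_um": (0.0, 10.0)},
        {"bin_factor": 0},
        {"filament_width_px": 4},  # must be odd
        {"poisson_scale": -1.0},
        {"gaussian_noise_sd": -0.5},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationParams(**kwargs)


class TestSimulateNetwork:
    def test_default_network_has_fifty_segments(self):
        net = simulate_network(SimulationParams(rng_seed=0))
        assert len(net) == 50  # 25 seeds + 1 daughter each
        assert len(net.seeds) == 25
        assert len(net.daughters) == 25

    def test_zero_seeds_gives_empty_network(self):
        net = simulate_network(SimulationParams(n_seed_filaments=0, rng_seed=0))
        assert len(net) == 0

    def test_deterministic_under_seed(self):
        p = SimulationParams(rng_seed=7)
        assert simulate_network(p).segments == simulate_network(p).segments

    def test_different_seeds_differ(self):
        a = simulate_network(SimulationParams(rng_seed=1))
        b = simulate_network(SimulationParams(rng_seed=2))
        assert a.segments != b.segments

    def test_endpoints_inside_field(self):
        net = simulate_network(SimulationParams(rng_seed=5))
        w, h = net.field_size_um
        for s in net.segments:
            for x, y in (s.start, s.end):
                assert -1e-9 <= x <= w + 1e-9
                assert -1e-9 <= y <= h + 1e-9

    def test_parent_precedes_daughter(self):
        net = simulate_network(SimulationParams(rng_seed=5))
        for i, s in enumerate(net.segments):
            if s.parent_index is not None:
                assert s.parent_index < i
                assert net.segments[s.parent_index].parent_index is None

    @pytest.mark.parametrize("seed", range(5))
    def test_branch_angle_exact_on_vectors(self, seed):
        """Daughter leaves its parent at exactly the branch angle."""
        p = SimulationParams(rng_seed=seed, branch_angle_deg=70.0)
        net = simulate_network(p)
        for d in net.daughters:
            parent = net.segments[d.parent_index]
            delta = (d.angle_rad - parent.angle_rad) % (2 * math.pi)
            angle = math.degrees(min(delta, 2 * math.pi - delta))
            assert angle == pytest.approx(70.0, abs=1e-9)

    def test_branch_point_lies_on_parent(self):
        net = simulate_network(SimulationParams(rng_seed=11))
        for d in net.daughters:
            parent = net.segments[d.parent_index]
            (x0, y0), (x1, y1) = parent.start, parent.end
            bx, by = d.start
            cross = (x1 - x0) * (by - y0) - (y1 - y0) * (bx - x0)
            assert abs(cross) < 1e-9 * max(1.0, parent.length)


class TestRasterize:
    def test_horizontal_segment_stripe_width(self, small_params):
        """A dilated horizontal line is exactly filament_width_px tall."""
        net = FilamentNetwork(
            (Segment((0.2, 1.0), (1.8, 1.0), None),), (2.0, 2.0)
        )
        mask = rasterize(net, small_params)
        mid_cols = mask[:, 80:120]
        heights = mid_cols.sum(axis=0)
        assert np.all(heights == small_params.filament_width_px)

    def test_empty_network_all_zero(self, small_params):
        net = FilamentNetwork((), (2.0, 2.0))
        assert not rasterize(net, small_params).any()

    def test_crossing_segments_make_four_pockets(self, small_params):
        """Around an X crossing the background splits into 4 components."""
        net = FilamentNetwork(
            (
                Segment((0.2, 1.0), (1.8, 1.0), None),
                Segment((1.0, 0.2), (1.0, 1.8), None),
            ),
            (2.0, 2.0),
        )
        mask = rasterize(net, small_params)
        window = mask[70:130, 70:130]
        _, n = ndi.label(~window)
        assert n == 4

    def test_matches_full_grid_disk_dilation(self, small_params):
        """Per-point offset dilation equals scipy's morphological dilation."""
        net = simulate_network(small_params)
        fast = rasterize(net, small_params)
        thin = np.zeros(small_params.raster_shape, bool)
        scale = 1000.0 / small_params.raster_pixel_nm
        n = small_params.raster_shape[0]
        for s in net.segments:
            rr, cc = draw_line(
                min(int(round(s.start[1] * scale)), n - 1),
                min(int(round(s.start[0] * scale)), n - 1),
                min(int(round(s.end[1] * scale)), n - 1),
                min(int(round(s.end[0] * scale)), n - 1),
            )
            thin[rr, cc] = True
        radius = (small_params.filament_width_px - 1) // 2
        ref = ndi.binary_dilation(thin, structure=disk(radius))
        assert np.array_equal(fast, ref)


class TestBinImage:
    def test_constant_image_unchanged(self):
        assert np.array_equal(bin_image(np.ones((4, 4)), 2), np.ones((2, 2)))

    def test_intensity_conserved(self, rng):
        raster = rng.random((37, 53))  # not divisible by 5: exercises padding
        binned = bin_image(raster, 5)
        assert binned.sum() * 25 == pytest.approx(raster.sum())

    def test_checkerboard_bins_to_half(self):
        cb = np.indices((8, 8)).sum(axis=0) % 2
        assert np.array_equal(bin_image(cb, 2), np.full((4, 4), 0.5))

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            bin_image(np.ones((4, 4)), 0)


class TestEmulateMicroscope:
    def test_identity_when_all_stages_off(self, rng):
        p = SimulationParams(
            psf_sigma_nm=0.0, poisson_scale=0.0,
            gaussian_noise_sd=0.0, smoothing_sigma_px=0.0,
        )
        img = rng.random((32, 32))
        assert np.array_equal(emulate_microscope(img, p), img)

    def test_blur_preserves_mass_and_symmetry(self):
        p = SimulationParams(
            poisson_scale=0.0, gaussian_noise_sd=0.0, smoothing_sigma_px=0.0,
            psf_sigma_nm=130.0,  # 2 binned px
        )
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = emulate_microscope(img, p)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        assert np.allclose(out, out[::-1]) and np.allclose(out, out[:, ::-1])
        assert out[20, 20] == out.max()

    def test_poisson_stage_mean_matches_scaled_input(self):
        """Monte-Carlo: E[Poisson(scale * I)] = scale * I within 3 SE."""
        p = SimulationParams(
            psf_sigma_nm=0.0, gaussian_noise_sd=0.0, smoothing_sigma_px=0.0,
            poisson_scale=50.0,
        )
        img = np.full((20, 20), 2.0)
        rng = np.random.default_rng(0)
        reps = 1000
        total = np.zeros_like(img)
        for _ in range(reps):
            total += emulate_microscope(img, p, rng=rng)
        grand_mean = total.mean() / reps
        expected = 100.0
        se = math.sqrt(expected / (reps * img.size))
        assert abs(grand_mean - expected) < 3 * se

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            emulate_microscope(np.array([[-1.0, 0.0]]), SimulationParams())


class TestPipeline:
    def test_pair_masks_bit_identical_under_seed(self, small_params):
        a = simulate_pair(small_params)
        b = simulate_pair(small_params)
        assert np.array_equal(a.ground_truth_mask, b.ground_truth_mask)
        assert np.array_equal(a.emulated_image, b.emulated_image)

    def test_pixel_size_is_raster_times_bin(self, small_params):
        pair = simulate_pair(small_params)
        assert pair.pixel_size_um == pytest.approx(
            small_params.raster_pixel_nm * small_params.bin_factor / 1000.0
        )

    def test_density_series_segment_counts(self, small_params):
        series = make_density_series(
            [5, 10, 15, 20, 25], params=small_params, rng_seed=0
        )
        assert [len(p.network) for p in series] == [10, 20, 30, 40, 50]
        for pair in series:  # noise off: rendering is deterministic, >= 0
            assert np.all(pair.emulated_image >= 0)

    def test_density_series_zero_count_blank(self, small_params):
        (pair,) = make_density_series([0], params=small_params)
        assert not pair.ground_truth_mask.any()
        assert pair.emulated_image.max() == 0

    def test_coverage_monotone_in_seed_count(self, small_params):
        """Mean filament-occupied area grows with seed count (>= 10 seeds)."""
        counts = [4, 8, 12]
        cover = np.zeros((10, len(counts)))
        for i in range(10):
            series = make_density_series(counts, params=small_params, rng_seed=100 + i)
            cover[i] = [p.ground_truth_mask.sum() for p in series]
        assert np.all(np.diff(cover.mean(axis=0)) > 0)

    def test_empty_seed_counts_rejected(self):
        with pytest.raises(ValueError):
            make_density_series([])
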