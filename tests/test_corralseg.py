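"""Corral segmentation: grid oracles, partition, monotonicity, matching."""

import itertools
import math

import numpy as np
import pytest

from cortexmesh import (
    Corral,
    CorralParams,
    CorralSet,
    SimulationParams,
    compare_conditions,
    make_fixture,
    match_corrals,
    segment_corrals,
    simulate_pair,
    summarize_roi,
)

PX = 0.065  # um, camera-scale pixel


def _plain_params(**kw):
    defaults = dict(
        threshold_method="manual", manual_threshold=0.5,
        erosion_iterations=0, min_corral_area_um2=0.0,
    )
    defaults.update(kw)
    return CorralParams(**defaults)


class TestSegmentCorrals:
    def test_blank_image_is_one_corral(self):
        cs = segment_corrals(np.zeros((64, 64)), PX, _plain_params())
        assert len(cs) == 1
        assert cs.corrals[0].pixel_count == 64 * 64
        assert cs.corrals[0].touches_border

    def test_constant_image_otsu_fails(self):
        with pytest.raises(ValueError, match="threshold undefined"):
            segment_corrals(np.ones((32, 32)), PX)

    def test_full_filament_mask_gives_empty_set(self):
        with pytest.warns(UserWarning, match="corral space is empty"):
            cs = segment_corrals(
                np.ones((16, 16)), PX, _plain_params(manual_threshold=0.5)
            )
        assert len(cs) == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_grid_oracle_exact_cells(self, k):
        """k lines per direction fence exactly (k+1)^2 pixel-exact cells."""
        img, ann = make_fixture("grid_mesh", k=k)
        cs = segment_corrals(img, PX, _plain_params())
        interior = [c for c in cs.corrals if not c.touches_border]
        assert len(interior) == (k + 1) ** 2 == ann["n_cells"]
        for c in interior:
            assert c.pixel_count == ann["cell_area_px"]
            assert c.area_um2 == pytest.approx(ann["cell_area_px"] * PX**2)

    def test_area_is_pixel_count_times_pixel_area(self, default_pair):
        cs = segment_corrals(default_pair.emulated_image, PX)
        for c in cs.corrals:
            assert c.area_um2 == pytest.approx(c.pixel_count * PX**2)
        labels = [c.label for c in cs.corrals]
        assert len(labels) == len(set(labels))

    def test_partition_tiles_roi(self, default_pair):
        """Corral pixels + filament mask + watershed lines tile the ROI."""
        cs = segment_corrals(
            default_pair.emulated_image, PX,
            CorralParams(min_corral_area_um2=0.0),
        )
        corral_px = cs.label_image > 0
        filament_px = cs.filament_mask
        assert not (corral_px & filament_px).any()
        lines_px = ~(corral_px | filament_px)
        assert corral_px.sum() + filament_px.sum() + lines_px.sum() == corral_px.size
        # watershed lines are sparse separators, not a third phase
        assert lines_px.sum() < 0.1 * corral_px.size

    def test_min_area_filter_removes_small_regions(self):
        img, _ = make_fixture("grid_mesh", k=3, cell_px=5)
        big = segment_corrals(img, PX, _plain_params())
        filt = segment_corrals(
            img, PX, _plain_params(min_corral_area_um2=26 * PX**2)
        )
        assert len(big) > len(filt) == 0 or all(
            c.pixel_count >= 26 for c in filt.corrals
        )

    def test_exclude_border_drops_flagged_regions(self):
        cs = segment_corrals(
            np.zeros((64, 64)), PX, _plain_params(exclude_border=True)
        )
        assert len(cs) == 0


@pytest.fixture(scope="module")
def sim_image():
    pair = simulate_pair(SimulationParams(rng_seed=77))
    return pair.emulated_image, pair.pixel_size_um


class TestMonotonicity:
    def test_threshold_monotone_total_corral_area(self, sim_image):
        """Raising the threshold frees filament pixels into corral space."""
        img, ps = sim_image
        base = segment_corrals(img, ps, CorralParams(erosion_iterations=0))
        totals = []
        for scale in (0.6, 1.0, 1.4):
            cs = segment_corrals(
                img, ps,
                _plain_params(manual_threshold=base.threshold_used * scale),
            )
            totals.append(cs.areas_um2(include_border=True).sum())
        assert np.all(np.diff(totals) >= 0)

    def test_erosion_monotone_total_corral_area(self, sim_image):
        img, ps = sim_image
        totals = []
        for it in (0, 1, 2):
            cs = segment_corrals(
                img, ps,
                CorralParams(erosion_iterations=it, min_corral_area_um2=0.0),
            )
            totals.append(cs.areas_um2(include_border=True).sum())
        assert np.all(np.diff(totals) >= 0)


def _corral_set(areas_um2):
    corrals = [
        Corral(i + 1, a, 4 * math.sqrt(a), (0.0, 0.0), int(a / PX**2), False)
        for i, a in enumerate(areas_um2)
    ]
    return CorralSet(
        corrals, (10, 10), PX, CorralParams(), np.zeros((10, 10), np.int32),
        np.zeros((10, 10), bool),
    )


class TestSummaries:
    def test_summary_of_known_areas(self):
        s = summarize_roi(_corral_set([1.0, 2.0, 3.0]))
        assert s["n_corrals"] == 3
        assert s["mean_area_um2"] == pytest.approx(2.0)
        assert s["sd_area_um2"] == pytest.approx(1.0)

    def test_empty_set_flagged_with_nan_means(self):
        s = summarize_roi(_corral_set([]))
        assert s["n_corrals"] == 0
        assert math.isnan(s["mean_area_um2"])

    def test_identical_groups_compare_null(self):
        g = [{"n_corrals": n, "mean_area_um2": a, "mean_perimeter_um": p}
             for n, a, p in [(10, 1.0, 4.0), (12, 1.2, 4.2), (11, 1.1, 4.1)]]
        tab = compare_conditions(g, g)
        assert np.allclose(tab["difference"], 0.0)
        assert np.allclose(tab["p_value"], 1.0)

    def test_textbook_t_test(self):
        """{1,2,3} vs {4,5,6}: difference 3, pooled t = 3/sqrt(2/3)."""
        a = [{"m": v} for v in (1.0, 2.0, 3.0)]
        b = [{"m": v} for v in (4.0, 5.0, 6.0)]
        tab = compare_conditions(a, b, metrics=["m"])
        row = tab.iloc[0]
        assert row["difference"] == pytest.approx(3.0)
        # pooled variance 1.0 -> SEM sqrt(2/3), t = 3 / sqrt(2/3)
        assert row["sem_difference"] == pytest.approx(math.sqrt(2 / 3))
        assert row["t"] == pytest.approx(3.0 / math.sqrt(2 / 3))
        assert row["p_value"] == pytest.approx(0.02131164, rel=1e-5)

    def test_mismatched_metrics_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compare_conditions(
                [{"x": 1}, {"x": 2}], [{"y": 1}, {"y": 2}], metrics=["x"]
            )

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([{"x": 1}], [{"x": 1}, {"x": 2}], metrics=["x"])


def _brute_force_match(ref, det, min_overlap):
    """Exhaustive optimal one-to-one assignment maximising total IoU."""
    ref_labels = sorted(set(ref.ravel()) - {0})
    det_labels = sorted(set(det.ravel()) - {0})
    ious = {}
    for r in ref_labels:
        for d in det_labels:
            inter = np.count_nonzero((ref == r) & (det == d))
            if inter:
                union = np.count_nonzero((ref == r) | (det == d))
                iou = inter / union
                if iou >= min_overlap:
                    ious[(r, d)] = iou
    best, best_score = [], -1.0
    k = min(len(ref_labels), len(det_labels))
    for size in range(k + 1):
        for rsub in itertools.combinations(ref_labels, size):
            for dperm in itertools.permutations(det_labels, size):
                pairs = list(zip(rsub, dperm))
                if any(p not in ious for p in pairs):
                    continue
                score = sum(ious[p] for p in pairs)
                if score > best_score:
                    best_score, best = score, pairs
    return set(best)


class TestMatching:
    def test_self_match_is_perfect(self, default_pair):
        cs = segment_corrals(default_pair.emulated_image, PX)
        rep = match_corrals(cs, cs, min_overlap=0.5)
        assert rep.unmatched_reference == rep.unmatched_detected == 0
        assert all(ov == pytest.approx(1.0) for _, _, ov in rep.pairs)
        assert rep.area_bias_um2 == pytest.approx(0.0)

    def test_missing_region_counts_unmatched(self):
        ref = np.zeros((20, 20), int)
        ref[2:8, 2:8] = 1
        ref[12:18, 12:18] = 2
        det = np.where(ref == 1, 1, 0)
        rep = match_corrals(ref, det, min_overlap=0.5)
        assert len(rep.pairs) == 1
        assert rep.unmatched_reference == 1
        assert rep.unmatched_detected == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_corrals(np.zeros((4, 4), int), np.zeros((5, 5), int))

    @pytest.mark.parametrize("trial", range(15))
    def test_greedy_equals_exhaustive_optimum(self, trial):
        """At IoU >= 0.5 pairs are exclusive: greedy = brute-force optimum."""
        rng = np.random.default_rng(trial)
        shape = (24, 24)
        blocks = np.repeat(np.repeat(rng.integers(0, 5, (4, 4)), 6, 0), 6, 1)
        ref = blocks
        # detected = reference with labels shuffled and pixels perturbed
        perm = rng.permutation(5)
        det = perm[blocks]
        flip = rng.random(shape) < 0.15
        det = np.where(flip, rng.integers(0, 5, shape), det)
        rep = match_corrals(ref, det, min_overlap=0.5)
        assert set((r, d) for r, d, _ in rep.pairs) == _brute_force_match(
            ref, det, 0.5
        )
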