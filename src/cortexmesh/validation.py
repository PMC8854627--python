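"""Simulation studies validating the two analysis workflows.

Each study regenerates synthetic meshworks from scratch, runs the relevant
workflow, and returns summary statistics:

* :func:`recovery_study` — does corral segmentation of microscope-emulated
  images recover the corral areas of the matched ground-truth masks?
* :func:`density_monotonicity_study` — does the random-line peak count rise,
  and the inter-peak distance fall, with true filament density?
* :func:`underestimation_study` — peak counts per chord against the true
  number of filament-chord crossings (the method undercounts by design).
* :func:`disruption_study` — does a sparser ("drug-disrupted") mesh read out
  as fewer, larger corrals?
* :func:`monotonicity_suite` — threshold / erosion monotonicity of total
  corral area on random simulated images.

Both arms of the recovery and disruption studies are segmented without
erosion: at the simulator's 65 nm camera pixel a single-pixel erosion
removes 65 nm of filament — several times the half-width bias that Otsu
segmentation of the blurred filaments introduces — so it over-merges pores
on this pixel scale (see the methods note).  On real SRRF reconstructions,
whose pixels are several-fold finer, the default single erosion stands.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .corralseg import CorralParams, compare_conditions, segment_corrals, summarize_roi
from .linedensity import DensityParams, density_analysis, detect_peaks, profile_and_normalize, random_line
from .netsim import SimulationParams, make_density_series, simulate_pair

__all__ = [
    "recovery_study",
    "density_monotonicity_study",
    "underestimation_study",
    "disruption_study",
    "monotonicity_suite",
]

#: Segmentation used on simulated data (both arms): Otsu for the emulated
#: image (reduces to the 0/1 split on the binary mask), no erosion at the
#: coarse camera-pixel scale, standard sub-resolution area filter.
SIM_SEG_PARAMS = CorralParams(erosion_iterations=0)

_GT_SEG_PARAMS = replace(
    SIM_SEG_PARAMS, threshold_method="manual", manual_threshold=0.5
)


def recovery_study(
    n_networks: int = 30,
    seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> dict:
    """Ground-truth recovery: corral areas, emulated vs ground truth.

    Simulates ``n_networks`` meshworks (default conditions: 25 seeds + 1
    daughter each at 70 degrees), segments mask and emulated image with the
    same parameters, and compares the per-image mean corral areas
    (border-touching pores excluded).
    """
    base = params or SimulationParams()
    gt_means, pr_means = [], []
    for i in range(n_networks):
        pair = simulate_pair(replace(base, rng_seed=seed + i))
        gt = segment_corrals(
            pair.ground_truth_mask.astype(float), pair.pixel_size_um, _GT_SEG_PARAMS
        )
        pr = segment_corrals(pair.emulated_image, pair.pixel_size_um, SIM_SEG_PARAMS)
        gt_means.append(float(np.mean(gt.areas_um2(include_border=False))))
        pr_means.append(float(np.mean(pr.areas_um2(include_border=False))))
    gt_means = np.array(gt_means)
    pr_means = np.array(pr_means)
    return {
        "n_networks": n_networks,
        "gt_mean_area_um2": float(gt_means.mean()),
        "gt_sd_area_um2": float(gt_means.std(ddof=1)),
        "processed_mean_area_um2": float(pr_means.mean()),
        "processed_sd_area_um2": float(pr_means.std(ddof=1)),
        "mean_difference_um2": float((pr_means - gt_means).mean()),
        "per_image_gt": gt_means,
        "per_image_processed": pr_means,
    }


def density_monotonicity_study(
    seed_counts: Sequence[int] = (5, 10, 15, 20, 25),
    n_seeds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Peak count and inter-peak distance across a mesh-density series.

    For each rng seed, renders the noise-free density series and runs the
    random-line analysis with ``n_repeats`` chords per image; reports the
    per-condition means (averaged over seeds) and the number of adjacent
    condition pairs violating monotonicity (expected: 0).
    """
    counts = np.zeros((n_seeds, len(seed_counts)))
    dists = np.zeros_like(counts)
    for i in range(n_seeds):
        series = make_density_series(seed_counts, rng_seed=seed + i)
        for j, pair in enumerate(series):
            res = density_analysis(
                pair.emulated_image,
                DensityParams(n_repeats=n_repeats, rng_seed=seed + 97 * i + j),
                pair.pixel_size_um,
            )
            counts[i, j] = res.mean_peak_count
            dists[i, j] = res.mean_inter_peak_distance_um
    mean_counts = counts.mean(axis=0)
    mean_dists = dists.mean(axis=0)
    return {
        "seed_counts": list(seed_counts),
        "mean_peak_counts": mean_counts,
        "mean_inter_peak_distances_um": mean_dists,
        "count_violations": int(np.sum(np.diff(mean_counts) < 0)),
        "distance_violations": int(np.sum(np.diff(mean_dists) > 0)),
    }


def underestimation_study(n_chords: int = 1000, seed: int = 0) -> dict:
    """Detected peaks per chord vs true filament-chord crossings.

    Chords are drawn over a noise-free emulated meshwork; truth is counted
    geometrically on the vector network.  The analysis is expected to
    undercount (PSF merging, threshold) — it is a relative density metric,
    not a filament counter.
    """
    (pair,) = make_density_series([25], rng_seed=seed)
    rng = np.random.default_rng(seed + 1)
    ps = pair.pixel_size_um
    shape = pair.emulated_image.shape
    detected, true = [], []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_chords):
            ends = random_line(shape, rng, min_line_length=0.25 * min(shape))
            prof = profile_and_normalize(pair.emulated_image, ends)
            pk = detect_peaks(prof, 0.1, ps)
            detected.append(pk.positions.size)
            (r0, c0), (r1, c1) = ends
            true.append(
                pair.network.count_chord_crossings(
                    (c0 * ps, r0 * ps), (c1 * ps, r1 * ps)
                )
            )
    return {
        "n_chords": n_chords,
        "mean_detected_peaks": float(np.mean(detected)),
        "mean_true_crossings": float(np.mean(true)),
    }


def disruption_study(n_rois: int = 10, seed: int = 0) -> dict:
    """Sparse ("disrupted", 10-seed) vs dense ("control", 25-seed) meshes.

    Mirrors a drug-disruption experiment: fewer filaments leave fewer,
    larger corrals.  Returns the per-metric contrast with Student's t-test.
    """

    def rois(n_seed: int, offset: int) -> list[dict]:
        out = []
        for i in range(n_rois):
            pair = simulate_pair(
                SimulationParams(n_seed_filaments=n_seed, rng_seed=seed + offset + i)
            )
            cs = segment_corrals(pair.emulated_image, pair.pixel_size_um, SIM_SEG_PARAMS)
            out.append(summarize_roi(cs))
        return out

    control = rois(25, 0)
    disrupted = rois(10, 10_000)
    table = compare_conditions(control, disrupted)
    by_metric = {row["metric"]: row for _, row in table.iterrows()}
    return {
        "n_rois": n_rois,
        "table": table,
        "area_increase_um2": float(by_metric["mean_area_um2"]["difference"]),
        "area_p": float(by_metric["mean_area_um2"]["p_value"]),
        "count_change": float(by_metric["n_corrals"]["difference"]),
        "count_p": float(by_metric["n_corrals"]["p_value"]),
    }


def monotonicity_suite(n_images: int = 20, seed: int = 0) -> dict:
    """Threshold / erosion monotonicity of total corral area.

    A higher filament threshold or one more erosion strictly shrinks the
    filament mask, so the total pore area must not decrease.  Counted over
    ``n_images`` random simulated meshworks; expected violations: 0.
    """
    thr_viol = 0
    ero_viol = 0
    for i in range(n_images):
        pair = simulate_pair(SimulationParams(rng_seed=seed + i))
        img, ps = pair.emulated_image, pair.pixel_size_um
        base = segment_corrals(img, ps, CorralParams(erosion_iterations=0))
        totals = []
        for scale in (0.7, 1.0, 1.3):
            cs = segment_corrals(
                img, ps,
                CorralParams(
                    threshold_method="manual",
                    manual_threshold=base.threshold_used * scale,
                    erosion_iterations=0,
                    min_corral_area_um2=0.0,
                ),
            )
            totals.append(cs.areas_um2(include_border=True).sum())
        if not np.all(np.diff(totals) >= -1e-9):
            thr_viol += 1
        totals = []
        for it in (0, 1, 2):
            cs = segment_corrals(
                img, ps,
                CorralParams(erosion_iterations=it, min_corral_area_um2=0.0),
            )
            totals.append(cs.areas_um2(include_border=True).sum())
        if not np.all(np.diff(totals) >= -1e-9):
            ero_viol += 1
    return {
        "n_images": n_images,
        "threshold_violations": thr_viol,
        "erosion_violations": ero_viol,
    }
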