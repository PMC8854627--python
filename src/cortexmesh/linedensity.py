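"""Filament-density profiling by repeated random line profiles.

Designed for expansion-microscopy/SIM images whose mesh is too discontinuous
for pore segmentation: random chords are drawn across the ROI, the intensity
along each chord is min-max normalised, and every local maximum above a
background threshold is counted as one filament crossing — deliberately with
no prominence cutoff, so closely adjacent but still separate filaments are
resolved.  The per-chord peak counts and inter-peak distances, pooled over
~100 repeats, serve as a relative density metric for comparing images
(e.g. an actin vs a microtubule network); they underestimate true filament
number and are not an absolute count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import signal, stats

__all__ = [
    "DensityParams",
    "LineProfile",
    "PeakSet",
    "DensityResult",
    "random_line",
    "profile_and_normalize",
    "detect_peaks",
    "density_analysis",
    "compare_density",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityParams:
    """Parameters of one density analysis run.

    ``min_line_length_px = None`` rejects chords shorter than a quarter of
    the shorter ROI side, so every profile samples a representative stretch
    of the mesh.  ``baseline_threshold`` is on the normalised [0, 1] scale;
    only maxima strictly above it are counted.
    """

    n_repeats: int = 100
    baseline_threshold: float = 0.1
    sampling_step_px: float = 1.0
    min_line_length_px: Optional[float] = None
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0.0 <= self.baseline_threshold < 1.0):
            raise ValueError("baseline_threshold must lie in [0, 1)")
        if self.sampling_step_px <= 0:
            raise ValueError("sampling_step_px must be > 0")


class LineProfile(NamedTuple):
    """Intensity profile along one chord, raw and min-max normalised."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]  # ((r, c), (r, c))
    positions_px: np.ndarray  # distance along the chord, strictly increasing
    raw_intensity: np.ndarray
    normalized_intensity: np.ndarray


class PeakSet(NamedTuple):
    """Peaks of one profile; lengths in um when ``pixel_size_um`` was given."""

    positions: np.ndarray  # sorted, along-line coordinate
    heights: np.ndarray  # normalised intensity at each peak
    prominences: np.ndarray
    widths_at_half_prominence: np.ndarray
    inter_peak_distances: np.ndarray  # consecutive position differences
    unit: str  # "px" or "um"


@dataclass
class DensityResult:
    """Pooled result of ``n_repeats`` random line profiles of one image."""

    per_repeat: list[dict]  # endpoints, peak_count, distances (um)
    params: DensityParams
    pixel_size_um: float

    @property
    def peak_counts(self) -> np.ndarray:
        return np.array([r["peak_count"] for r in self.per_repeat])

    @property
    def pooled_distances_um(self) -> np.ndarray:
        if not self.per_repeat:
            return np.empty(0)
        return np.concatenate(
            [np.asarray(r["distances_um"]) for r in self.per_repeat]
        )

    @property
    def mean_peak_count(self) -> float:
        return float(self.peak_counts.mean())

    @property
    def sd_peak_count(self) -> float:
        n = len(self.per_repeat)
        return float(self.peak_counts.std(ddof=1)) if n > 1 else 0.0

    @property
    def mean_inter_peak_distance_um(self) -> float:
        d = self.pooled_distances_um
        return float(d.mean()) if d.size else float("nan")

    @property
    def sd_inter_peak_distance_um(self) -> float:
        d = self.pooled_distances_um
        return float(d.std(ddof=1)) if d.size > 1 else float("nan")

    def summary(self) -> dict:
        return {
            "n_repeats": len(self.per_repeat),
            "mean_peak_count": self.mean_peak_count,
            "sd_peak_count": self.sd_peak_count,
            "mean_inter_peak_distance_um": self.mean_inter_peak_distance_um,
            "sd_inter_peak_distance_um": self.sd_inter_peak_distance_um,
        }


def random_line(
    roi_shape: tuple[int, int],
    rng: np.random.Generator,
    min_line_length: float = 0.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Draw one random chord across the ROI.

    The two endpoints land on two distinct sides of the image boundary (the
    side of each endpoint uniform over the four sides, the position uniform
    along the side), so every line spans the full ROI.  Chords shorter than
    ``min_line_length`` are rejected and redrawn.  Returns ((r0, c0),
    (r1, c1)) in pixel coordinates.
    """
    h, w = roi_shape
    if h < 2 or w < 2:
        raise ValueError("ROI must be at least 2x2 px")

    def point_on_edge(edge: int) -> tuple[float, float]:
        if edge == 0:  # top
            return (0.0, rng.uniform(0, w - 1))
        if edge == 1:  # bottom
            return (float(h - 1), rng.uniform(0, w - 1))
        if edge == 2:  # left
            return (rng.uniform(0, h - 1), 0.0)
        return (rng.uniform(0, h - 1), float(w - 1))  # right

    while True:
        e0 = int(rng.integers(4))
        e1 = int((e0 + 1 + rng.integers(3)) % 4)  # distinct side, uniform
        p0 = point_on_edge(e0)
        p1 = point_on_edge(e1)
        if np.hypot(p1[0] - p0[0], p1[1] - p0[1]) >= min_line_length:
            return (p0, p1)


def profile_and_normalize(
    image: np.ndarray,
    endpoints,
    sampling_step: float = 1.0,
) -> LineProfile:
    """Sample the image along a chord and min-max normalise to [0, 1].

    Bilinear interpolation at ``sampling_step`` px intervals.  A constant
    profile normalises to all zeros (with a warning): it carries no peaks.
    Normalisation is idempotent.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    (r0, c0), (r1, c1) = endpoints
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError("endpoints must lie inside the image")
    length = float(np.hypot(r1 - r0, c1 - c0))
    n = max(2, int(np.floor(length / sampling_step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    raw = ndi.map_coordinates(img, np.vstack([rows, cols]), order=1)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        norm = (raw - lo) / (hi - lo)
    else:
        warnings.warn("constant intensity profile; normalised to flat zero")
        norm = np.zeros_like(raw)
    return LineProfile((tuple(endpoints[0]), tuple(endpoints[1])), t * length, raw, norm)


def detect_peaks(
    profile,
    baseline_threshold: float = 0.1,
    pixel_size_um: Optional[float] = None,
) -> PeakSet:
    """Find all local maxima above the background threshold.

    Every strict local maximum (plateaux count once, at their midpoint) with
    normalised height strictly above ``baseline_threshold`` is a peak — no
    prominence cutoff is applied, so two peaks separated by a shallow saddle
    remain two peaks.  Prominence is measured down to the higher of the two
    flanking saddles; width is taken at half prominence by linear
    interpolation, the saddle bounding the evaluation of merged peaks.
    """
    if isinstance(profile, LineProfile):
        y = np.asarray(profile.normalized_intensity, dtype=np.float64)
        pos = np.asarray(profile.positions_px, dtype=np.float64)
    else:
        y = np.asarray(profile, dtype=np.float64)
        pos = np.arange(y.size, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty profile")

    idx, _props = signal.find_peaks(y)  # all local maxima, plateau midpoints
    keep = y[idx] > baseline_threshold
    idx = idx[keep]
    prom = signal.peak_prominences(y, idx)[0] if idx.size else np.empty(0)
    if idx.size:
        widths = signal.peak_widths(y, idx, rel_height=0.5)[0]
    else:
        widths = np.empty(0)

    step = float(pos[1] - pos[0]) if pos.size > 1 else 1.0
    scale = (pixel_size_um or 1.0)
    positions = pos[idx] * scale
    widths_phys = widths * step * scale
    return PeakSet(
        positions=positions,
        heights=y[idx],
        prominences=prom,
        widths_at_half_prominence=widths_phys,
        inter_peak_distances=np.diff(positions),
        unit="um" if pixel_size_um else "px",
    )


def density_analysis(
    image: np.ndarray,
    params: Optional[DensityParams] = None,
    pixel_size_um: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> DensityResult:
    """Repeat random-chord peak counting over one image.

    Each of ``params.n_repeats`` chords is profiled, normalised and peak
    counted; per-chord counts and inter-peak distances are pooled into the
    summary statistics.  Deterministic under ``params.rng_seed``.
    """
    params = params or DensityParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    min_len = params.min_line_length_px
    if min_len is None:
        min_len = 0.25 * min(img.shape)

    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # blank chords warn once each otherwise
        for _ in range(params.n_repeats):
            ends = random_line(img.shape, rng, min_line_length=min_len)
            prof = profile_and_normalize(img, ends, params.sampling_step_px)
            peaks = detect_peaks(prof, params.baseline_threshold, pixel_size_um)
            records.append(
                {
                    "endpoints": ends,
                    "peak_count": int(peaks.positions.size),
                    "distances_um": peaks.inter_peak_distances,
                }
            )
    return DensityResult(records, params, pixel_size_um)


def compare_density(
    result_a: DensityResult,
    result_b: DensityResult,
    expansion_factor: Optional[float] = None,
    n_bins: int = 20,
) -> dict:
    """Compare two density analyses (e.g. actin vs microtubule networks).

    Reports per-image mean +/- SD of peak count and inter-peak distance,
    Student's t-tests on the per-repeat counts and pooled distances, and
    shared-bin histogram counts ready for plotting.  Distances are raw
    (sample scale); when ``expansion_factor`` is given, biological-scale
    values (raw / factor) are reported alongside.
    """
    if len(result_a.per_repeat) != len(result_b.per_repeat):
        raise ValueError("results must come from the same n_repeats policy")

    counts_a, counts_b = result_a.peak_counts, result_b.peak_counts
    dist_a, dist_b = result_a.pooled_distances_um, result_b.pooled_distances_um
    t_c, p_c = stats.ttest_ind(counts_a, counts_b, equal_var=True)

    if dist_a.size > 1 and dist_b.size > 1:
        t_d, p_d = stats.ttest_ind(dist_a, dist_b, equal_var=True)
    else:
        t_d, p_d = float("nan"), float("nan")

    def hist(x, lo, hi):
        counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
        return {"bin_edges": edges, "counts": counts}

    all_counts = np.concatenate([counts_a, counts_b])
    out = {
        "mean_peak_count_a": result_a.mean_peak_count,
        "sd_peak_count_a": result_a.sd_peak_count,
        "mean_peak_count_b": result_b.mean_peak_count,
        "sd_peak_count_b": result_b.sd_peak_count,
        "peak_count_t": float(t_c),
        "peak_count_p": float(p_c),
        "mean_distance_a_um": result_a.mean_inter_peak_distance_um,
        "sd_distance_a_um": result_a.sd_inter_peak_distance_um,
        "mean_distance_b_um": result_b.mean_inter_peak_distance_um,
        "sd_distance_b_um": result_b.sd_inter_peak_distance_um,
        "distance_t": float(t_d),
        "distance_p": float(p_d),
        "peak_count_hist_a": hist(counts_a, all_counts.min(), all_counts.max() + 1),
        "peak_count_hist_b": hist(counts_b, all_counts.min(), all_counts.max() + 1),
    }
    if dist_a.size and dist_b.size:
        lo = min(dist_a.min(), dist_b.min())
        hi = max(dist_a.max(), dist_b.max())
        out["distance_hist_a"] = hist(dist_a, lo, hi)
        out["distance_hist_b"] = hist(dist_b, lo, hi)
    if expansion_factor is not None:
        if expansion_factor <= 0:
            raise ValueError("expansion_factor must be > 0")
        for key in (
            "mean_distance_a_um", "sd_distance_a_um",
            "mean_distance_b_um", "sd_distance_b_um",
        ):
            out[key + "_corrected"] = out[key] / expansion_factor
        out["expansion_factor"] = expansion_factor
    return out
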