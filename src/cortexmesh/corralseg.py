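"""Corral (mesh pore) segmentation of super-resolved cortical actin images.

The workflow mirrors the classic FIJI recipe for quantifying the holes of the
actin mesh: Otsu (or manual) threshold to isolate filament pixels, binary
erosion of the filament mask, then a distance-transform watershed of the
complementary "corral space" to split pores that merge through gaps in the
mesh.  Each resulting region ("particle") is measured in physical units.

Also provides batch summaries of ROI-level corral statistics, a plain
two-sample comparison for condition contrasts (e.g. cytochalasin-D-treated
vs control cells), and one-to-one matching of detected corrals against a
reference segmentation for validation on simulated ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, local_maxima
from skimage.segmentation import watershed

__all__ = [
    "CorralParams",
    "Corral",
    "CorralSet",
    "MatchReport",
    "segment_corrals",
    "summarize_roi",
    "compare_conditions",
    "match_corrals",
]

log = logging.getLogger(__name__)

#: Default lateral resolution estimate (um) for SRRF-like inputs, used to set
#: the sub-resolution corral filter when none is given explicitly.
DEFAULT_RESOLUTION_UM = 0.150


@dataclass(frozen=True)
class CorralParams:
    """Parameters of one corral segmentation run.

    ``min_corral_area_um2 = None`` applies a sub-resolution filter of
    ``(2 * resolution_um)**2 / 4`` (the area of a square whose side is the
    resolution) — pores smaller than that cannot be trusted in a
    resolution-limited image and are discarded.
    """

    threshold_method: str = "otsu"  # "otsu" | "manual"
    manual_threshold: Optional[float] = None
    otsu_scale: float = 1.0
    erosion_iterations: int = 1
    erosion_element: str = "cross3"  # "cross3" | "disk_r"
    erosion_disk_radius: int = 1
    min_corral_area_um2: Optional[float] = None
    resolution_um: float = DEFAULT_RESOLUTION_UM
    exclude_border: bool = False
    #: minimum separation (px) between watershed seed maxima; closer maxima
    #: are merged into one seed, curbing over-segmentation of rough pores
    seed_min_separation_px: int = 3

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "manual"):
            raise ValueError("threshold_method must be 'otsu' or 'manual'")
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ValueError("manual_threshold required when method='manual'")
        if self.erosion_element not in ("cross3", "disk_r"):
            raise ValueError("erosion_element must be 'cross3' or 'disk_r'")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")
        if self.min_corral_area_um2 is not None and self.min_corral_area_um2 < 0:
            raise ValueError("min_corral_area_um2 must be >= 0")
        if self.otsu_scale <= 0:
            raise ValueError("otsu_scale must be > 0")

    def effective_min_area_um2(self) -> float:
        if self.min_corral_area_um2 is not None:
            return self.min_corral_area_um2
        return (2.0 * self.resolution_um) ** 2 / 4.0


@dataclass(frozen=True)
class Corral:
    """One segmented mesh pore, geometry in physical units."""

    label: int
    area_um2: float
    perimeter_um: float
    centroid_xy_um: tuple[float, float]
    pixel_count: int
    touches_border: bool


@dataclass
class CorralSet:
    """All corrals of one ROI plus the label image that defines them.

    ``label_image`` is 0 on filament pixels, watershed separation lines and
    any region removed by the size filter; positive values are corral labels.
    ``filament_mask`` is the (eroded) binary filament mask the watershed ran
    against, kept so that mask + corrals + watershed lines can be audited to
    tile the ROI exactly.
    """

    corrals: list[Corral]
    roi_shape: tuple[int, int]
    pixel_size_um: float
    params: CorralParams
    label_image: np.ndarray
    filament_mask: np.ndarray
    threshold_used: float = float("nan")

    def __len__(self) -> int:
        return len(self.corrals)

    def areas_um2(self, include_border: bool = True) -> np.ndarray:
        return np.array(
            [c.area_um2 for c in self.corrals if include_border or not c.touches_border]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "area_um2": c.area_um2,
                "perimeter_um": c.perimeter_um,
                "centroid_x_um": c.centroid_xy_um[0],
                "centroid_y_um": c.centroid_xy_um[1],
                "pixel_count": c.pixel_count,
                "touches_border": c.touches_border,
            }
            for c in self.corrals
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "label", "area_um2", "perimeter_um", "centroid_x_um",
                "centroid_y_um", "pixel_count", "touches_border",
            ],
        )


@dataclass(frozen=True)
class MatchReport:
    """One-to-one correspondence between a reference and a detected set."""

    pairs: list[tuple[int, int, float]]  # (reference label, detected label, IoU)
    unmatched_reference: int
    unmatched_detected: int
    area_bias_um2: float  # mean(detected - reference) area over matched pairs


_CROSS3 = ndi.generate_binary_structure(2, 1)


def _erosion_structure(params: CorralParams) -> np.ndarray:
    if params.erosion_element == "cross3":
        return _CROSS3
    return disk(params.erosion_disk_radius).astype(bool)


def _watershed_corral_space(
    corral_space: np.ndarray, min_separation: int
) -> np.ndarray:
    """Distance-transform watershed of the pore space.

    Seeds are the connected local-maximum plateaus of the Euclidean distance
    transform; plateaus closer than ``min_separation`` px are merged into one
    seed (FIJI's binary watershed behaves comparably via its ultimate eroded
    points).  Watershed lines are kept (label 0) so regions stay disjoint.
    """
    edt = ndi.distance_transform_edt(corral_space)
    maxima = local_maxima(edt, connectivity=2) & corral_space
    if min_separation > 1:
        radius = max(1, min_separation // 2)
        merged = ndi.binary_dilation(maxima, structure=disk(radius))
    else:
        merged = maxima
    markers, n = ndi.label(merged, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.zeros_like(corral_space, dtype=np.int32)
    return watershed(-edt, markers, mask=corral_space, watershed_line=True)


def segment_corrals(
    image: np.ndarray,
    pixel_size_um: float,
    params: Optional[CorralParams] = None,
) -> CorralSet:
    """Segment the mesh pores ("corrals") of one 2D grayscale ROI.

    Pipeline: threshold -> filament mask -> erosion -> watershed of the
    complement -> region measurement.  Erosion treats out-of-field as
    filament so the image frame is not etched into an artificial pore ring.
    Regions below the sub-resolution area filter are dropped; regions
    touching the image border are flagged (and removed entirely when
    ``params.exclude_border``) because an open-edged pore has no defined
    area.
    """
    params = params or CorralParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    if params.threshold_method == "otsu":
        if img.max() == img.min():
            raise ValueError("threshold undefined: image is constant")
        thr = threshold_otsu(img) * params.otsu_scale
    else:
        thr = float(params.manual_threshold)

    filament = img > thr
    if params.erosion_iterations > 0 and filament.any():
        filament = ndi.binary_erosion(
            filament,
            structure=_erosion_structure(params),
            iterations=params.erosion_iterations,
            border_value=1,
        )
    corral_space = ~filament

    if not corral_space.any():
        warnings.warn("corral space is empty: no pores below the threshold mask")
        return CorralSet(
            [], img.shape, pixel_size_um, params,
            np.zeros(img.shape, np.int32), filament, thr,
        )

    labels = _watershed_corral_space(corral_space, params.seed_min_separation_px)

    min_area_px = params.effective_min_area_um2() / pixel_size_um**2
    corrals: list[Corral] = []
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    nrows, ncols = labels.shape
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols
        if touches and params.exclude_border:
            continue
        keep[rp.label] = True
        cy, cx = rp.centroid
        corrals.append(
            Corral(
                label=int(rp.label),
                area_um2=float(rp.area) * pixel_size_um**2,
                perimeter_um=float(rp.perimeter) * pixel_size_um,
                centroid_xy_um=(cx * pixel_size_um, cy * pixel_size_um),
                pixel_count=int(rp.area),
                touches_border=bool(touches),
            )
        )
    labels = np.where(keep[labels], labels, 0).astype(np.int32)
    return CorralSet(corrals, img.shape, pixel_size_um, params, labels, filament, thr)


def summarize_roi(cs: CorralSet, include_border: bool = False) -> dict:
    """ROI-level summary row: corral count, mean/SD area and perimeter.

    Border-touching corrals are excluded by default (their area is an
    artefact of the crop).  An empty set yields count 0 with NaN means.
    """
    sel = [c for c in cs.corrals if include_border or not c.touches_border]
    areas = np.array([c.area_um2 for c in sel])
    perims = np.array([c.perimeter_um for c in sel])
    n = len(sel)
    def _m(x):
        return float(np.mean(x)) if n else float("nan")
    def _s(x):
        return float(np.std(x, ddof=1)) if n > 1 else (0.0 if n == 1 else float("nan"))
    return {
        "n_corrals": n,
        "mean_area_um2": _m(areas),
        "sd_area_um2": _s(areas),
        "mean_perimeter_um": _m(perims),
        "sd_perimeter_um": _s(perims),
    }


_DEFAULT_METRICS = ("n_corrals", "mean_area_um2", "mean_perimeter_um")


def compare_conditions(
    summaries_a: Sequence[dict],
    summaries_b: Sequence[dict],
    metrics: Sequence[str] = _DEFAULT_METRICS,
) -> pd.DataFrame:
    """Two-sample comparison of per-ROI summaries between two conditions.

    For each metric: group means and SDs, the difference of means (B - A)
    with its pooled-variance SEM, and a Student's t-test p-value.  Requires
    at least two ROIs per condition.
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValueError("need >= 2 ROIs per condition")
    for m in metrics:
        for group in (summaries_a, summaries_b):
            if any(m not in s for s in group):
                raise ValueError(f"metric {m!r} missing from a summary")
    rows = []
    for m in metrics:
        a = np.array([s[m] for s in summaries_a], dtype=float)
        b = np.array([s[m] for s in summaries_b], dtype=float)
        na, nb = len(a), len(b)
        sp2 = (
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        sem_diff = float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
        t, p = stats.ttest_ind(b, a, equal_var=True)
        rows.append(
            {
                "metric": m,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "difference": b.mean() - a.mean(),
                "sem_difference": sem_diff,
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def _label_image_of(x) -> tuple[np.ndarray, Optional[float]]:
    if isinstance(x, CorralSet):
        return x.label_image, x.pixel_size_um
    return np.asarray(x), None


def match_corrals(
    reference: Union[CorralSet, np.ndarray],
    detected: Union[CorralSet, np.ndarray],
    min_overlap: float = 0.5,
) -> MatchReport:
    """Greedy one-to-one matching of detected corrals to a reference set.

    Candidate pairs are scored by intersection-over-union of their pixel
    sets; pairs are accepted in order of descending IoU (ties broken by
    ascending reference then detected label) and rejected below
    ``min_overlap``.  At ``min_overlap >= 0.5`` the greedy assignment is
    provably the unique maximal one, since IoU > 0.5 pairs are exclusive.

    ``area_bias_um2`` is the mean detected-minus-reference area over matched
    pairs, in um^2 when a pixel size is available (px^2 otherwise).
    """
    ref, ps_ref = _label_image_of(reference)
    det, ps_det = _label_image_of(detected)
    if ref.shape != det.shape:
        raise ValueError("reference and detected label images differ in shape")
    ps = ps_ref or ps_det or 1.0

    both = (ref > 0) & (det > 0)
    pairs_flat = ref[both].astype(np.int64) * (det.max() + 1) + det[both]
    uniq, inter = np.unique(pairs_flat, return_counts=True)
    ref_lab = (uniq // (det.max() + 1)).astype(int)
    det_lab = (uniq % (det.max() + 1)).astype(int)
    ref_area = np.bincount(ref.ravel())
    det_area = np.bincount(det.ravel())
    iou = inter / (ref_area[ref_lab] + det_area[det_lab] - inter)

    order = np.lexsort((det_lab, ref_lab, -iou))
    used_ref: set[int] = set()
    used_det: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        if iou[i] < min_overlap:
            continue
        rl, dl = int(ref_lab[i]), int(det_lab[i])
        if rl in used_ref or dl in used_det:
            continue
        used_ref.add(rl)
        used_det.add(dl)
        pairs.append((rl, dl, float(iou[i])))

    n_ref = int(np.count_nonzero(ref_area[1:] if len(ref_area) > 1 else []))
    n_det = int(np.count_nonzero(det_area[1:] if len(det_area) > 1 else []))
    if pairs:
        bias_px = np.mean([det_area[d] - ref_area[r] for r, d, _ in pairs])
        bias = float(bias_px) * ps**2
    else:
        bias = float("nan")
    return MatchReport(
        pairs=pairs,
        unmatched_reference=n_ref - len(pairs),
        unmatched_detected=n_det - len(pairs),
        area_bias_um2=bias,
    )
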