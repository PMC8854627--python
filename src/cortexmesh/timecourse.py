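"""Frame-by-frame corral analysis of live-cell super-resolved stacks.

Each frame of a (T, Y, X) stack is segmented independently with shared
parameters; a corral of interest, picked by a point in frame 0, is then
followed through time by greedy spatial-overlap linking, yielding its
area-versus-time trace (the live-imaging readout of mesh remodelling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .corralseg import CorralParams, CorralSet, segment_corrals, summarize_roi

__all__ = ["TrackResult", "analyze_stack", "track_corral"]

log = logging.getLogger(__name__)


@dataclass
class TrackResult:
    """Per-frame segmentations plus one corral's trajectory.

    ``tracked`` holds one (frame_index, label_or_None, area_um2_or_nan)
    triple per frame; the label is None from the first frame at which the
    link broke (best overlap below the threshold).
    """

    per_frame: list[CorralSet]
    tracked: list[tuple[int, Optional[int], float]]
    seed_point: tuple[int, int]
    frame_interval_s: Optional[float] = None

    def area_series_um2(self) -> np.ndarray:
        return np.array([a for _, _, a in self.tracked])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, lab, area in self.tracked:
            row = {"frame": f, "label": lab, "area_um2": area}
            if self.frame_interval_s is not None:
                row["time_s"] = f * self.frame_interval_s
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_stack(
    stack: np.ndarray,
    pixel_size_um: float,
    params: Optional[CorralParams] = None,
) -> list[CorralSet]:
    """Segment every frame of a (T, Y, X) stack independently."""
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ValueError("expected a (T, Y, X) stack")
    if arr.shape[0] < 1:
        raise ValueError("stack must contain at least one frame")
    return [segment_corrals(frame, pixel_size_um, params) for frame in arr]


def stack_summary(per_frame: Sequence[CorralSet]) -> pd.DataFrame:
    """Per-frame summary table (corral count, mean area/perimeter)."""
    rows = []
    for i, cs in enumerate(per_frame):
        row = {"frame": i}
        row.update(summarize_roi(cs))
        rows.append(row)
    return pd.DataFrame(rows)


def _label_at(cs: CorralSet, point: tuple[int, int]) -> int:
    r, c = int(point[0]), int(point[1])
    if not (0 <= r < cs.label_image.shape[0] and 0 <= c < cs.label_image.shape[1]):
        raise ValueError("seed_point outside the image")
    return int(cs.label_image[r, c])


def track_corral(
    per_frame: Sequence[CorralSet],
    seed_point: tuple[int, int],
    min_overlap: float = 0.3,
) -> TrackResult:
    """Follow one corral through a segmented stack.

    ``seed_point`` is a (row, col) pixel inside the corral of interest in
    frame 0; landing on a filament or watershed-line pixel is an error that
    names the nearest corral instead.  Linking is greedy: in each next frame
    the label with the largest pixel overlap against the current region is
    taken (ties by larger intersection, then smaller label) provided the
    overlap covers at least ``min_overlap`` of the current region; otherwise
    the track ends.  When a corral splits, the larger-overlap child is
    followed.
    """
    if not per_frame:
        raise ValueError("per_frame is empty")
    first = per_frame[0]
    label0 = _label_at(first, seed_point)
    if label0 == 0:
        nz = first.label_image > 0
        if not nz.any():
            raise ValueError("seed_point is not inside a corral (frame 0 has none)")
        _, (ir, ic) = ndi.distance_transform_edt(~nz, return_indices=True)
        near = int(first.label_image[ir[seed_point], ic[seed_point]])
        raise ValueError(
            f"seed_point lies on a filament/boundary pixel; nearest corral is "
            f"label {near}"
        )

    area_by_label = [
        {c.label: c.area_um2 for c in cs.corrals} for cs in per_frame
    ]
    tracked: list[tuple[int, Optional[int], float]] = [
        (0, label0, area_by_label[0].get(label0, float("nan")))
    ]
    current = per_frame[0].label_image == label0
    for f in range(1, len(per_frame)):
        nxt = per_frame[f].label_image
        overlap = nxt[current]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            tracked.append((f, None, float("nan")))
            current = np.zeros_like(current)
            continue
        counts = np.bincount(overlap)
        best = int(np.argmax(counts))  # argmax takes the smallest label on ties
        frac = counts[best] / current.sum()
        if frac < min_overlap:
            tracked.append((f, None, float("nan")))
            current = np.zeros_like(current)
            continue
        tracked.append((f, best, area_by_label[f].get(best, float("nan"))))
        current = nxt == best
    return TrackResult(list(per_frame), tracked, (int(seed_point[0]), int(seed_point[1])))
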