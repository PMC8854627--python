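"""Deterministic synthetic fixtures with machine-readable ground truth.

These constructions back the exact oracles of the analysis modules: square
grid meshes with a known number of pores, equally spaced parallel filaments
with a known spacing, and small time-lapse stacks in which a pore splits or
the mesh decays frame by frame.  All are generated in memory; nothing is
read from disk.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from scipy import ndimage as ndi

__all__ = ["make_fixture"]


def _grid_mesh(k: int = 3, cell_px: int = 20, line_width: int = 3, intensity: float = 1.0):
    """Square mesh with a border frame and k interior lines per direction.

    The frame plus k lines each way fence off exactly (k + 1)^2 fully
    enclosed square cells of ``cell_px`` x ``cell_px`` pixels, none touching
    the image border.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n_lines = k + 2  # frame lines included
    size = (k + 1) * cell_px + n_lines * line_width
    img = np.zeros((size, size), dtype=np.float64)
    starts = [i * (cell_px + line_width) for i in range(n_lines)]
    for s in starts:
        img[s : s + line_width, :] = intensity
        img[:, s : s + line_width] = intensity
    annotation = {
        "kind": "grid_mesh",
        "k": k,
        "n_cells": (k + 1) ** 2,
        "cell_area_px": cell_px * cell_px,
        "cell_px": cell_px,
        "line_width": line_width,
        "size": size,
    }
    return img, annotation


def _parallel_filaments(
    spacing_px: int = 20,
    n_filaments: int = 5,
    line_width: int = 3,
    height: int = 128,
    margin: int = 10,
    intensity: float = 1.0,
):
    """Vertical filaments at exactly ``spacing_px`` centre-to-centre."""
    width = 2 * margin + (n_filaments - 1) * spacing_px + line_width
    img = np.zeros((height, width), dtype=np.float64)
    half = line_width // 2
    centers = [margin + half + i * spacing_px for i in range(n_filaments)]
    for c in centers:
        img[:, c - half : c - half + line_width] = intensity
    annotation = {
        "kind": "parallel_filaments",
        "spacing_px": spacing_px,
        "n_filaments": n_filaments,
        "centers_px": centers,
        "line_width": line_width,
    }
    return img, annotation


def _mask_cell_stats(img: np.ndarray) -> tuple[int, float]:
    """Count and mean pixel area of enclosed background cells (flood-fill)."""
    labels, n = ndi.label(img == 0)
    # discard components touching the border: open-edged, not enclosed
    border = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    areas = [
        int((labels == i).sum()) for i in range(1, n + 1) if i not in border
    ]
    if not areas:
        return 0, float("nan")
    return len(areas), float(np.mean(areas))


def _split_corral_stack(frames: int = 6, split_frame: int = 3, cell_px: int = 40, line_width: int = 3):
    """A single pore that gains a dividing wall at ``split_frame``.

    The wall is placed off-centre so the two children differ in size and a
    tracker has an unambiguous larger child to follow.
    """
    base, _ = _grid_mesh(k=0, cell_px=cell_px, line_width=line_width)
    split = base.copy()
    wall = line_width + (2 * cell_px) // 3  # off-centre divider
    split[:, wall : wall + line_width] = base.max()
    stack = np.stack([base if f < split_frame else split for f in range(frames)])
    left = wall - line_width
    right = cell_px - left - line_width
    annotation = {
        "kind": "split_corral_stack",
        "frames": frames,
        "split_frame": split_frame,
        "cells_before": 1,
        "cells_after": 2,
        "child_areas_px": [left * cell_px, right * cell_px],
        "larger_child": "left" if left > right else "right",
        "cell_px": cell_px,
        "line_width": line_width,
    }
    return stack, annotation


def _decay_stack(frames: int = 10, cell_px: int = 16, line_width: int = 3):
    """Mesh losing one wall segment per frame: pores pairwise merge and grow.

    Emulates progressive filament loss under an actin-disrupting drug.  Each
    frame removes the first interior vertical wall segment of a different
    row band, so every merge joins exactly two cells into one clean 2:1
    rectangle; the ground-truth mean enclosed-cell area strictly increases.
    """
    k = frames - 1  # one band per frame needs k + 1 >= frames bands
    img0, _ = _grid_mesh(k=k, cell_px=cell_px, line_width=line_width)
    starts = [i * (cell_px + line_width) for i in range(k + 2)]
    wall0 = starts[1]  # first interior vertical wall
    stack = []
    counts, means = [], []
    img = img0.copy()
    for f in range(frames):
        stack.append(img.copy())
        n, mean_a = _mask_cell_stats(img)
        counts.append(n)
        means.append(mean_a)
        band_rows = slice(starts[f] + line_width, starts[f + 1])
        img = img.copy()
        img[band_rows, wall0 : wall0 + line_width] = 0.0
    annotation = {
        "kind": "decay_stack",
        "frames": frames,
        "cell_counts": counts,
        "mean_cell_areas_px": means,
        "cell_px": cell_px,
        "line_width": line_width,
    }
    return np.stack(stack), annotation


_KINDS = {
    "grid_mesh": _grid_mesh,
    "parallel_filaments": _parallel_filaments,
    "split_corral_stack": _split_corral_stack,
    "decay_stack": _decay_stack,
}


def make_fixture(kind: str, **params: Any):
    """Build a named fixture; returns (image_or_stack, annotation dict)."""
    try:
        builder = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}"
        ) from None
    return builder(**params)
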