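"""Image I/O with physical-unit metadata.

Thin wrappers around :mod:`tifffile` that normalise single-plane and T-stack
grayscale TIFFs to float arrays with (T,)Y,X axes and carry the pixel size
(um/px) through reads and writes, trying OME, ImageJ and resolution-tag
metadata in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

__all__ = ["ImageMeta", "read_image", "write_image"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImageMeta:
    pixel_size_um: Optional[float]
    frame_interval_s: Optional[float]
    source_path: Optional[str]
    bit_depth: int
    axes: str  # "YX" or "TYX"


def _pixel_size_from_tif(tif: tifffile.TiffFile) -> Optional[float]:
    # OME-XML physical size
    try:
        if tif.ome_metadata:
            import re

            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tif.ome_metadata)
            if m:
                return float(m.group(1))
    except Exception:  # pragma: no cover - malformed metadata
        pass
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            px = den / num  # pixels per unit -> unit per pixel
            unit = None
            if tif.imagej_metadata:
                unit = tif.imagej_metadata.get("unit")
            if unit in ("um", "micron", "µm"):
                return px
            if "ResolutionUnit" in tags:
                ru = tags["ResolutionUnit"].value
                ru = getattr(ru, "value", ru)
                if ru == 3:  # centimetre
                    return px * 1e4
    return None


def read_image(
    path: Union[str, Path],
    pixel_size_um: Optional[float] = None,
) -> tuple[np.ndarray, ImageMeta]:
    """Read a single- or multi-frame grayscale TIFF.

    Returns a float64 array shaped (Y, X) or (T, Y, X) plus metadata.  An
    explicit ``pixel_size_um`` overrides whatever the file carries.  RGB
    input is rejected (extract one channel first); the raw dynamic range is
    preserved (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        bit_depth = int(data.dtype.itemsize * 8)
        meta_px = _pixel_size_from_tif(tif)
        interval = None
        if tif.imagej_metadata:
            interval = tif.imagej_metadata.get("finterval")
    if "S" in axes or "C" in axes or (data.ndim == 3 and data.shape[-1] in (3, 4)):
        raise ValueError(
            "RGB/multi-channel TIFF: extract a single channel before analysis"
        )
    if data.ndim == 2:
        norm_axes = "YX"
    elif data.ndim == 3:
        norm_axes = "TYX"
    else:
        raise ValueError(f"unsupported TIFF dimensionality: {data.shape}")
    meta = ImageMeta(
        pixel_size_um=pixel_size_um if pixel_size_um is not None else meta_px,
        frame_interval_s=interval,
        source_path=str(path),
        bit_depth=bit_depth,
        axes=norm_axes,
    )
    return data.astype(np.float64), meta


def write_image(
    path: Union[str, Path],
    array: np.ndarray,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    dtype=np.uint16,
) -> None:
    """Write a (T,)Y,X array as an ImageJ-compatible TIFF.

    Integer targets get the array rescaled to the full dtype range when it
    is float (labels and masks pass through unscaled when already integer).
    Pixel size goes into the resolution tags with a micron unit.
    """
    path = Path(path)
    a = np.asarray(array)
    if np.issubdtype(a.dtype, np.floating) and np.issubdtype(dtype, np.integer):
        lo, hi = float(a.min()), float(a.max())
        info = np.iinfo(dtype)
        if hi > lo:
            a = (a - lo) / (hi - lo) * info.max
        a = a.astype(dtype)
    else:
        a = a.astype(dtype)
    kwargs: dict = {"imagej": True}
    metadata: dict = {"axes": "TYX" if a.ndim == 3 else "YX"}
    if pixel_size_um:
        kwargs["resolution"] = (1.0 / pixel_size_um, 1.0 / pixel_size_um)
        metadata["unit"] = "um"
    if frame_interval_s:
        metadata["finterval"] = frame_interval_s
    kwargs["metadata"] = metadata
    tifffile.imwrite(path, a, **kwargs)
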