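"""Image and table I/O with physical pixel calibration.

Intensities are normalised to [0, 1] by dividing by the dtype maximum
(255 for 8-bit, 65535 for 16-bit) rather than by the per-image maximum,
so that one global threshold is comparable across a whole batch of
images. Pixel size (µm/pixel) is supplied by the caller per run; TIFF
resolution tags, when present, are only checked for consistency.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, ImageFormatError

__all__ = [
    "CalibratedImage",
    "load_image",
    "max_z_projection",
    "write_metrics_csv",
    "read_metrics_csv",
    "save_mask",
    "parse_sample_filename",
    "METRICS_CSV_COLUMNS",
]

#: Column order of the consolidated per-spheroid metrics table.
METRICS_CSV_COLUMNS = [
    "sample_id",
    "group",
    "n_outer_pixels",
    "area_day0_mm2",
    "area_day2_mm2",
    "delta_area_mm2",
    "outer_area_mm2",
    "mean_distance_mm",
    "max_distance_mm",
    "I_r_mm4",
    "pca_angle_max_deg",
    "pca_angle_min_deg",
    "I_max_mm4",
    "I_min_mm4",
    "mean_dist_max_mm",
    "mean_dist_min_mm",
    "moment_fold_change",
    "distance_fold_change",
]


@dataclass
class CalibratedImage:
    """A 2D raster with physical pixel calibration.

    Parameters
    ----------
    pixels
        2D float array of intensities in [0, 1], or a boolean array for
        binary images.
    pixel_size_um
        Physical edge length of one pixel in micrometres; must be > 0.
    id
        Sample / spheroid identifier (free text).
    timepoint_label
        Timepoint label such as ``"Day0"`` or ``"Day2"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    id: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise DimensionError("image must have at least one pixel")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(np.float64, copy=False)
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"grayscale intensities must lie in [0, 1]; got range [{lo}, {hi}]"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


_DTYPE_MAX = {np.uint8: 255.0, np.uint16: 65535.0}


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == bool:
        return arr
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ImageFormatError(f"unsupported image dtype {arr.dtype}; expected 8/16-bit or float")


def parse_sample_filename(path: str | Path) -> tuple[str, str]:
    """Split ``<sampleID>_<timepoint>`` from a filename stem.

    Returns ``(sample_id, timepoint_label)``; if the stem has no underscore
    the whole stem is the id and the timepoint is empty.
    """
    stem = Path(path).stem
    m = re.match(r"^(.*)_([^_]+)$", stem)
    if m:
        return m.group(1), m.group(2)
    return stem, ""


def _check_resolution_tags(path: Path, pixel_size_um: float) -> None:
    """Warn if TIFF resolution tags disagree with the configured pixel size by >1%."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            tag = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if tag is None:
                return
            num, den = tag.value
            if num == 0:
                return
            # pixels per unit -> um per pixel
            unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 2), None)
            if unit_um is None:
                return
            tag_um = unit_um * den / num
            if abs(tag_um - pixel_size_um) / pixel_size_um > 0.01:
                warnings.warn(
                    f"TIFF resolution tag implies {tag_um:.4g} um/px but config says "
                    f"{pixel_size_um:.4g} um/px; using the configured value",
                    stacklevel=3,
                )
    except Exception:  # noqa: BLE001 - tag dialects vary; tags are advisory only
        return


def load_image(
    path: str | Path,
    pixel_size_um: float,
    channel: int | None = None,
) -> CalibratedImage:
    """Load a single-channel TIFF/PNG as a :class:`CalibratedImage`.

    8- and 16-bit integer images are rescaled by their dtype maximum so
    intensities land in [0, 1]. Multi-channel images require an explicit
    ``channel`` index; there is no silent RGB-to-gray conversion.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        _check_resolution_tags(path, pixel_size_um)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ImageFormatError(
                f"{path.name} has {arr.shape[-1] if arr.shape[-1] <= 4 else arr.shape[0]} "
                "channels; pass an explicit channel index"
            )
        # channel-last (H, W, C) for small C, else channel-first stacks
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    elif arr.ndim != 2:
        raise ImageFormatError(f"{path.name}: expected 2D image, got shape {arr.shape}")
    sample_id, timepoint = parse_sample_filename(path)
    return CalibratedImage(
        pixels=_normalize(arr),
        pixel_size_um=pixel_size_um,
        id=sample_id,
        timepoint_label=timepoint,
    )


def max_z_projection(stack: Sequence[CalibratedImage]) -> CalibratedImage:
    """Per-pixel maximum across a z-stack of identically shaped slices."""
    if len(stack) == 0:
        raise DimensionError("max_z_projection requires at least one slice")
    first = stack[0]
    for img in stack[1:]:
        if img.pixels.shape != first.pixels.shape:
            raise DimensionError(
                f"slice shape {img.pixels.shape} differs from {first.pixels.shape}"
            )
        if img.pixel_size_um != first.pixel_size_um:
            raise DimensionError("slices must share a pixel size")
    out = np.maximum.reduce([np.asarray(img.pixels, dtype=float) for img in stack])
    return CalibratedImage(
        pixels=out,
        pixel_size_um=first.pixel_size_um,
        id=first.id,
        timepoint_label=first.timepoint_label,
    )


def save_mask(mask_pixels: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit TIFF/PNG (0/255) for audit."""
    path = Path(path)
    arr = (np.asarray(mask_pixels, dtype=bool).astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        iio.imwrite(path, arr)


def write_metrics_csv(rows: Iterable[dict], path: str | Path) -> None:
    """Write per-spheroid metric records to CSV (header always present).

    Numeric fields round-trip at 12 significant digits.
    """
    rows = list(rows)
    df = pd.DataFrame(rows, columns=METRICS_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
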