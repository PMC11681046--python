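"""Binarization of grayscale nuclear-stain projections.

The pipeline is: percentile contrast stretch, optional Gaussian
background subtraction, a user-chosen global threshold (default 0.16 on
the [0, 1] intensity range), an optional artifact-erasing mask supplied
as a file, and a circular field mask that removes corner/long-axis bias.

The threshold comparison is strict (``intensity > threshold``), so a
threshold of 1.0 always yields an empty mask. Background subtraction is
Gaussian-blur subtraction with sigma in pixels and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DimensionError
from .io_images import CalibratedImage

__all__ = [
    "BinarizeConfig",
    "BinaryMask",
    "enhance_contrast",
    "subtract_background",
    "apply_threshold",
    "apply_artifact_mask",
    "apply_circular_mask",
    "binarize_pipeline",
]


@dataclass
class BinarizeConfig:
    """Parameters of the binarization pipeline.

    threshold
        Global intensity threshold in [0, 1]; pixels strictly above it
        become foreground. Default 0.16.
    contrast_percentiles
        (low, high) percentiles for the linear contrast stretch.
    background_sigma_px
        Gaussian sigma (pixels) for background subtraction; 0 disables it.
    apply_circular_mask
        Whether to crop foreground to the inscribed circular field.
    """

    threshold: float = 0.16
    contrast_percentiles: tuple[float, float] = (1.0, 99.0)
    background_sigma_px: float = 0.0
    apply_circular_mask: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        lo, hi = self.contrast_percentiles
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"invalid contrast percentiles {self.contrast_percentiles}")
        if self.background_sigma_px < 0:
            raise ValueError("background_sigma_px must be >= 0")


@dataclass
class BinaryMask:
    """Boolean raster sharing shape and calibration with its source image."""

    pixels: np.ndarray
    pixel_size_um: float
    id: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise DimensionError(f"expected a 2D mask, got ndim={self.pixels.ndim}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def enhance_contrast(
    img: CalibratedImage, contrast_percentiles: tuple[float, float] = (1.0, 99.0)
) -> CalibratedImage:
    """Percentile-clipped linear stretch to the full [0, 1] range.

    The low percentile maps to 0 and the high percentile to 1; values
    outside are clipped. A constant image (zero dynamic range) is
    returned unchanged.
    """
    lo_p, hi_p = contrast_percentiles
    if not (0.0 <= lo_p < hi_p <= 100.0):
        raise ValueError(f"invalid contrast percentiles {(lo_p, hi_p)}")
    v = np.asarray(img.pixels, dtype=float)
    p_lo, p_hi = np.percentile(v, [lo_p, hi_p])
    if p_hi - p_lo < 1e-12:
        return CalibratedImage(v.copy(), img.pixel_size_um, img.id, img.timepoint_label)
    out = np.clip((v - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    return CalibratedImage(out, img.pixel_size_um, img.id, img.timepoint_label)


def subtract_background(img: CalibratedImage, background_sigma_px: float) -> CalibratedImage:
    """Subtract a Gaussian-smoothed copy to flatten slowly varying background.

    With ``sigma = 0`` this is the identity. Otherwise the smoothed image
    is subtracted, negatives are clipped to 0, and the result is rescaled
    so its maximum matches the input maximum (a constant image becomes
    all zeros).
    """
    if background_sigma_px < 0:
        raise ValueError("background_sigma_px must be >= 0")
    v = np.asarray(img.pixels, dtype=float)
    if background_sigma_px == 0:
        return CalibratedImage(v.copy(), img.pixel_size_um, img.id, img.timepoint_label)
    bg = ndimage.gaussian_filter(v, sigma=background_sigma_px)
    out = np.clip(v - bg, 0.0, None)
    peak = out.max()
    if peak > 0:
        out = out * (v.max() / peak)
    return CalibratedImage(np.clip(out, 0.0, 1.0), img.pixel_size_um, img.id, img.timepoint_label)


def apply_threshold(img: CalibratedImage, threshold: float) -> BinaryMask:
    """Global threshold: foreground iff intensity is strictly above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return BinaryMask(
        pixels=np.asarray(img.pixels, dtype=float) > threshold,
        pixel_size_um=img.pixel_size_um,
        id=img.id,
        timepoint_label=img.timepoint_label,
    )


def apply_artifact_mask(mask: BinaryMask, artifact_mask: BinaryMask) -> BinaryMask:
    """Erase artifact pixels: output = mask AND NOT artifact_mask."""
    if mask.pixels.shape != artifact_mask.pixels.shape:
        raise DimensionError(
            f"artifact mask shape {artifact_mask.pixels.shape} differs from "
            f"image shape {mask.pixels.shape}"
        )
    return BinaryMask(
        pixels=mask.pixels & ~artifact_mask.pixels,
        pixel_size_um=mask.pixel_size_um,
        id=mask.id,
        timepoint_label=mask.timepoint_label,
    )


def apply_circular_mask(mask: BinaryMask) -> BinaryMask:
    """Zero out pixels beyond the inscribed circular field.

    The circle is centred on the geometric image centre
    ((W-1)/2, (H-1)/2) in pixel-centre coordinates with radius
    min(H, W)/2; pixels strictly beyond the radius are set to False.
    This prevents bias towards the frame's long axis and corners.
    """
    h, w = mask.pixels.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return BinaryMask(
        pixels=mask.pixels & inside,
        pixel_size_um=mask.pixel_size_um,
        id=mask.id,
        timepoint_label=mask.timepoint_label,
    )


def binarize_pipeline(
    img: CalibratedImage,
    cfg: BinarizeConfig | None = None,
    artifact_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Full binarization: contrast stretch, background subtraction,
    global threshold, artifact erasure, circular field mask (in order)."""
    cfg = cfg or BinarizeConfig()
    img = enhance_contrast(img, cfg.contrast_percentiles)
    img = subtract_background(img, cfg.background_sigma_px)
    mask = apply_threshold(img, cfg.threshold)
    if artifact_mask is not None:
        mask = apply_artifact_mask(mask, artifact_mask)
    if cfg.apply_circular_mask:
        mask = apply_circular_mask(mask)
    return mask
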