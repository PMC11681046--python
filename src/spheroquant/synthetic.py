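"""Synthetic spheroid-image fixtures with analytically known metrics.

Generates Day-0/Day-2 mask or grayscale pairs whose invasion metrics
have closed-form or brute-force-computable ground truth, so the whole
pipeline is testable without microscopy data. Rasterization rule: a
pixel is foreground iff its centre satisfies the shape inequality
(pixel-centre coordinates, x = column, y = row).

Truth records carry both continuum closed forms (e.g. the annulus mean
distance (2/(r1²−r0²))·∫(r−r0)·r dr) and pixel-exact references
computed from the analytic geometry (d = r − r0 for a circular
boundary), so tests can state rasterization tolerances explicitly.
Identical specs (including seed) produce identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binarize import BinaryMask
from .errors import SpheroquantError
from .io_images import CalibratedImage
from .metrics import MM_PER_UM, OuterPixelSet

__all__ = [
    "Disk",
    "Ellipse",
    "Annulus",
    "Scattered",
    "SinglePixels",
    "FixtureSpec",
    "generate_pair",
    "grayscale_variant",
    "gaussian_cloud_pixelset",
]


@dataclass
class Disk:
    radius: float


@dataclass
class Ellipse:
    a: float  # semi-axis along orientation
    b: float
    orientation_deg: float = 0.0


@dataclass
class Annulus:
    """Invasion filling r0 < r <= r1 around the spheroid centre."""

    r0: float
    r1: float

    def __post_init__(self) -> None:
        if not self.r1 > self.r0:
            raise ValueError("annulus requires r1 > r0")


@dataclass
class Scattered:
    """Invading pixels from a (possibly anisotropic) Gaussian cloud.

    Offsets are drawn from N(0, diag(sigma_px², (sigma_px/axis_ratio)²))
    rotated by ``orientation_deg``; draws landing inside the spheroid or
    outside the frame are rejected and redrawn.
    """

    n: int
    sigma_px: float
    axis_ratio: float = 1.0
    orientation_deg: float = 0.0


@dataclass
class SinglePixels:
    """Explicit invading pixels given as (radius_px, angle_deg) pairs."""

    polar: Sequence[tuple[float, float]]


@dataclass
class FixtureSpec:
    """Recipe for one Day-0/Day-2 fixture pair."""

    image_shape: tuple[int, int] = (200, 200)  # (H, W)
    pixel_size_um: float = 1.0
    spheroid: Disk | Ellipse = field(default_factory=lambda: Disk(50.0))
    center: Optional[tuple[float, float]] = None  # (x, y); default image centre
    invasion: Annulus | Scattered | SinglePixels | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.image_shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return xx.astype(float), yy.astype(float)


def _rasterize_spheroid(spec: FixtureSpec) -> np.ndarray:
    cx, cy = spec.resolved_center()
    xx, yy = _grid(spec.image_shape)
    dx, dy = xx - cx, yy - cy
    sph = spec.spheroid
    if isinstance(sph, Disk):
        return dx**2 + dy**2 <= sph.radius**2
    if isinstance(sph, Ellipse):
        a = np.radians(sph.orientation_deg)
        u = np.cos(a) * dx + np.sin(a) * dy
        v = -np.sin(a) * dx + np.cos(a) * dy
        return (u / sph.a) ** 2 + (v / sph.b) ** 2 <= 1.0
    raise SpheroquantError(f"unknown spheroid shape {type(sph).__name__}")


def _annulus_truth(r0: float, r1: float, radii: np.ndarray, pixel_size_um: float) -> dict:
    """Continuum and pixel-exact annulus references (circular boundary)."""
    s = pixel_size_um * MM_PER_UM
    d_px = radii - r0
    # continuum closed forms
    mean_d_cont = (2.0 / (r1**2 - r0**2)) * ((r1**3 - r0**3) / 3.0 - r0 * (r1**2 - r0**2) / 2.0)
    u = r1 - r0
    I_r_cont = 2.0 * np.pi * (u**4 / 4.0 + r0 * u**3 / 3.0)
    return {
        "n_outer_pixels": int(radii.size),
        "mean_distance_px_exact": float(d_px.mean()) if radii.size else 0.0,
        "I_r_px4_exact": float(np.sum(d_px**2)),
        "mean_distance_px_continuum": float(mean_d_cont),
        "I_r_px4_continuum": float(I_r_cont),
        "mean_distance_mm_continuum": float(mean_d_cont * s),
        "I_r_mm4_continuum": float(I_r_cont * s**4),
    }


def generate_pair(spec: FixtureSpec) -> tuple[BinaryMask, BinaryMask, dict]:
    """Rasterize a fixture pair and its analytic truth record.

    Day-0 is the spheroid silhouette; Day-2 adds the invasion pixels.
    The truth record always contains exact areas and, for circular
    spheroids, per-pixel radial references (d = r − r0) plus continuum
    closed forms where the geometry admits them.
    """
    h, w = spec.image_shape
    cx, cy = spec.resolved_center()
    day0_px = _rasterize_spheroid(spec)
    inv = np.zeros_like(day0_px)
    truth: dict = {
        "center_px": [cx, cy],
        "pixel_size_um": spec.pixel_size_um,
        "seed": spec.seed,
    }
    circular = isinstance(spec.spheroid, Disk)
    r0 = spec.spheroid.radius if circular else None

    if isinstance(spec.invasion, Annulus):
        if not circular:
            raise SpheroquantError("annulus invasion requires a Disk spheroid")
        if spec.invasion.r0 != r0:
            raise SpheroquantError("annulus r0 must equal the disk radius")
        if cx - spec.invasion.r1 < 0 or cy - spec.invasion.r1 < 0 \
           or cx + spec.invasion.r1 > w - 1 or cy + spec.invasion.r1 > h - 1:
            raise SpheroquantError("annulus extends outside the image frame")
        xx, yy = _grid(spec.image_shape)
        r = np.hypot(xx - cx, yy - cy)
        inv = (r > spec.invasion.r0) & (r <= spec.invasion.r1)
        truth.update(_annulus_truth(r0, spec.invasion.r1, r[inv], spec.pixel_size_um))
    elif isinstance(spec.invasion, SinglePixels):
        pts = []
        for radius, angle_deg in spec.invasion.polar:
            a = np.radians(angle_deg)
            x = int(round(cx + radius * np.cos(a)))
            y = int(round(cy + radius * np.sin(a)))
            if not (0 <= x < w and 0 <= y < h):
                raise SpheroquantError(f"invasion pixel ({x}, {y}) outside the frame")
            inv[y, x] = True
            pts.append((x, y))
        if circular:
            d = [np.hypot(x - cx, y - cy) - r0 for x, y in pts]
            truth["distances_px_exact"] = [float(v) for v in d]
    elif isinstance(spec.invasion, Scattered):
        sc = spec.invasion
        rng = np.random.default_rng(spec.seed)
        a = np.radians(sc.orientation_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        sig = np.array([sc.sigma_px, sc.sigma_px / sc.axis_ratio])
        accepted: list[tuple[int, int]] = []
        seen = set()
        for _ in range(200):
            draws = (R @ (rng.standard_normal((sc.n * 2, 2)) * sig).T).T
            for ox, oy in draws:
                x, y = int(round(cx + ox)), int(round(cy + oy))
                if not (0 <= x < w and 0 <= y < h):
                    continue
                if circular and np.hypot(x - cx, y - cy) <= r0:
                    continue
                if not circular and day0_px[y, x]:
                    continue
                if (x, y) in seen:
                    continue
                seen.add((x, y))
                accepted.append((x, y))
                if len(accepted) == sc.n:
                    break
            if len(accepted) == sc.n:
                break
        else:
            raise SpheroquantError("scattered invasion: could not place requested pixels")
        for x, y in accepted:
            inv[y, x] = True
        if circular:
            arr = np.asarray(accepted, dtype=float)
            r = np.hypot(arr[:, 0] - cx, arr[:, 1] - cy)
            truth["mean_distance_px_exact"] = float((r - r0).mean())
            truth["I_r_px4_exact"] = float(np.sum((r - r0) ** 2))
        truth["population_angle_deg"] = sc.orientation_deg
        truth["population_moment_fold"] = sc.axis_ratio**2
    elif spec.invasion is not None:
        raise SpheroquantError(f"unknown invasion type {type(spec.invasion).__name__}")

    day2_px = day0_px | inv
    truth["area_day0_px2"] = int(day0_px.sum())
    truth["area_day2_px2"] = int(day2_px.sum())
    truth["delta_area_px2"] = int(day2_px.sum()) - int(day0_px.sum())
    s = spec.pixel_size_um * MM_PER_UM
    truth["delta_area_mm2"] = truth["delta_area_px2"] * s**2
    day0 = BinaryMask(day0_px, spec.pixel_size_um, id="synthetic", timepoint_label="Day0")
    day2 = BinaryMask(day2_px, spec.pixel_size_um, id="synthetic", timepoint_label="Day2")
    return day0, day2, truth


def grayscale_variant(
    day0: BinaryMask,
    day2: BinaryMask,
    noise_sigma: float = 0.0,
    nucleus_intensity: float = 0.8,
    background_intensity: float = 0.0,
    seed: int = 0,
) -> tuple[CalibratedImage, CalibratedImage]:
    """Flat-intensity grayscale renderings of a mask pair plus Gaussian noise.

    Foreground pixels take ``nucleus_intensity``, background takes
    ``background_intensity``; seeded N(0, noise_sigma²) noise is added
    and the result clipped to [0, 1].
    """
    if not (0.0 <= background_intensity < nucleus_intensity <= 1.0):
        raise ValueError("require 0 <= background < nucleus <= 1")
    rng = np.random.default_rng(seed)
    out = []
    for mask in (day0, day2):
        img = np.where(mask.pixels, nucleus_intensity, background_intensity).astype(float)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        out.append(
            CalibratedImage(
                np.clip(img, 0.0, 1.0),
                mask.pixel_size_um,
                id=mask.id,
                timepoint_label=mask.timepoint_label,
            )
        )
    return out[0], out[1]


def gaussian_cloud_pixelset(
    n: int,
    sigma_max_px: float,
    axis_ratio: float,
    orientation_deg: float,
    center: tuple[float, float] = (0.0, 0.0),
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[OuterPixelSet, dict]:
    """Anisotropic Gaussian point cloud as an :class:`OuterPixelSet`.

    Population truth: principal angle = ``orientation_deg`` (mod 180°)
    and moment fold change = ``axis_ratio²``. Distances/angles are taken
    about ``center``. Used for directionality tests where no boundary
    is involved.
    """
    rng = np.random.default_rng(seed)
    a = np.radians(orientation_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    sig = np.array([sigma_max_px, sigma_max_px / axis_ratio])
    offsets = (R @ (rng.standard_normal((n, 2)) * sig).T).T
    pts = offsets + np.asarray(center, dtype=float)
    s = pixel_size_um * MM_PER_UM
    r = np.linalg.norm(offsets, axis=1)
    ang = np.degrees(np.arctan2(offsets[:, 1], offsets[:, 0]))
    ang[ang >= 180.0] -= 360.0
    ops = OuterPixelSet(
        points=pts,
        distances_mm=r * s,
        angles_deg=ang,
        dA_mm2=s**2,
        pixel_size_um=pixel_size_um,
        boundary_ref="gaussian-cloud",
    )
    truth = {
        "population_angle_deg": ((orientation_deg + 90.0) % 180.0) - 90.0,
        "population_moment_fold": axis_ratio**2,
    }
    return ops, truth
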