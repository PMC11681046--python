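"""Pixel-based invasion metrics.

Every foreground pixel of the final-timepoint image lying outside the
aligned initial boundary (an "outer pixel") contributes a radial
distance d (measured along the ray from the Day-0 centroid through the
pixel, back to the last boundary crossing) and an angle θ. The metrics
are:

    ΔA   = Area(Day 2) − Area(Day 0)                     (stained area change)
    D̄    = mean of d over outer pixels
    I_r  = Σ_i d_i² · dA                                 (radial area moment)

with dA the physical area of one pixel. I_r weights far-invading area
quadratically, combining invasion area and distance into one
invasiveness number. No nucleus/cell objects are ever formed: metrics
depend only on the pixel set (segmentation-free contract).

Distances are reported in mm and moments in mm⁴; dA = (pixel_size_um/1000)².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .binarize import BinaryMask
from .boundary import SpheroidBoundary, ray_distances
from .errors import DimensionError, UndefinedAngleError

__all__ = [
    "OuterPixelSet",
    "InvasionMetrics",
    "find_outer_pixels",
    "pixel_angle",
    "area_change",
    "radial_moment",
    "summarize_invasion",
    "export_polar_data",
    "plot_polar",
]

MM_PER_UM = 1e-3


@dataclass
class OuterPixelSet:
    """Coordinates, radial distances and angles of all outer pixels.

    ``points`` are (x, y) pixel coordinates; ``distances_mm`` are radial
    distances past the boundary; ``angles_deg`` are measured about the
    Day-0 centroid in the image frame (x right, y down, so positive
    angles turn clockwise on screen), in [−180, 180). ``dA_mm2`` is the
    area of one pixel. ``fallback_flags`` marks pixels whose ray cast
    was numerically degenerate and fell back to nearest-edge distance.
    """

    points: np.ndarray  # (N, 2) pixel coordinates (x, y)
    distances_mm: np.ndarray
    angles_deg: np.ndarray
    dA_mm2: float
    pixel_size_um: float
    boundary_ref: str = ""
    fallback_flags: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.fallback_flags is None:
            self.fallback_flags = np.zeros(len(self.points), dtype=bool)
        self.fallback_flags = np.asarray(self.fallback_flags, dtype=bool)
        n = len(self.points)
        if not (len(self.distances_mm) == len(self.angles_deg) == len(self.fallback_flags) == n):
            raise ValueError("points/distances/angles/flags lengths differ")
        if n and self.distances_mm.min() < 0:
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def distances_px(self) -> np.ndarray:
        return self.distances_mm / (self.pixel_size_um * MM_PER_UM)


@dataclass
class InvasionMetrics:
    """Per-spheroid scalar invasion metrics (areas mm², distances mm, I_r mm⁴)."""

    area_day0_mm2: float
    area_day2_mm2: float
    delta_area_mm2: float
    outer_area_mm2: float
    n_outer_pixels: int
    mean_distance_mm: float
    max_distance_mm: float
    I_r_mm4: float
    zero_invasion: bool = False
    n_ray_fallback: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def pixel_angle(p: tuple[float, float], centroid: tuple[float, float]) -> float:
    """Angle of p about the centroid, degrees in [−180, 180), image frame."""
    dx = p[0] - centroid[0]
    dy = p[1] - centroid[1]
    if dx == 0 and dy == 0:
        raise UndefinedAngleError("angle undefined: point coincides with centroid")
    theta = np.degrees(np.arctan2(dy, dx))
    if theta >= 180.0:
        theta -= 360.0
    return float(theta)


def _angles(points: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    d = points - np.asarray(centroid)
    theta = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    theta[theta >= 180.0] -= 360.0
    return theta


def find_outer_pixels(day2_mask: BinaryMask, boundary: SpheroidBoundary) -> OuterPixelSet:
    """All Day-2 foreground pixels whose centre lies outside the boundary.

    The boundary must already be aligned to the Day-2 frame. Pixels
    exactly on the polygon count as inside and are excluded. For each
    outer pixel the radial distance (ray through the Day-0 centroid,
    last boundary crossing) and the angle about the centroid are
    computed. No connected-component labelling is involved.
    """
    rows, cols = np.nonzero(day2_mask.pixels)
    pts = np.column_stack([cols, rows]).astype(float)
    dA = (day2_mask.pixel_size_um * MM_PER_UM) ** 2
    if len(pts) == 0:
        return OuterPixelSet(np.empty((0, 2)), np.empty(0), np.empty(0), dA,
                             day2_mask.pixel_size_um, boundary.source_id)
    poly = boundary.polygon
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
    outer = pts[~inside]
    if len(outer) == 0:
        return OuterPixelSet(np.empty((0, 2)), np.empty(0), np.empty(0), dA,
                             day2_mask.pixel_size_um, boundary.source_id)
    d_px, _, flags = ray_distances(boundary, outer)
    return OuterPixelSet(
        points=outer,
        distances_mm=d_px * day2_mask.pixel_size_um * MM_PER_UM,
        angles_deg=_angles(outer, boundary.centroid),
        dA_mm2=dA,
        pixel_size_um=day2_mask.pixel_size_um,
        boundary_ref=boundary.source_id,
        fallback_flags=flags,
    )


def area_change(day0_mask: BinaryMask, day2_mask: BinaryMask) -> tuple[float, float, float]:
    """Stained areas at both timepoints and ΔA = A(Day2) − A(Day0), in mm²."""
    if day0_mask.pixels.shape != day2_mask.pixels.shape:
        raise DimensionError(
            f"mask shapes differ: {day0_mask.pixels.shape} vs {day2_mask.pixels.shape}"
        )
    if day0_mask.pixel_size_um != day2_mask.pixel_size_um:
        raise DimensionError("masks must share a pixel size")
    dA = (day0_mask.pixel_size_um * MM_PER_UM) ** 2
    a0 = day0_mask.foreground_count * dA
    a2 = day2_mask.foreground_count * dA
    delta = a2 - a0
    if delta < 0:
        warnings.warn(
            f"negative area change ({delta:.3g} mm2) for sample "
            f"{day0_mask.id!r}: Day-2 stained area is smaller than Day-0",
            stacklevel=2,
        )
    return a0, a2, delta


def radial_moment(ops: OuterPixelSet) -> float:
    """Radial area moment of inertia I_r = Σ d² · dA (mm⁴); 0 for an empty set."""
    if len(ops) == 0:
        return 0.0
    return float(np.sum(ops.distances_mm**2) * ops.dA_mm2)


def summarize_invasion(
    day0_mask: BinaryMask,
    day2_mask: BinaryMask,
    boundary: SpheroidBoundary,
    ops: OuterPixelSet,
) -> InvasionMetrics:
    """Assemble the per-spheroid invasion record from its components."""
    a0, a2, delta = area_change(day0_mask, day2_mask)
    n = len(ops)
    zero = n == 0
    return InvasionMetrics(
        area_day0_mm2=a0,
        area_day2_mm2=a2,
        delta_area_mm2=delta,
        outer_area_mm2=n * ops.dA_mm2,
        n_outer_pixels=n,
        mean_distance_mm=0.0 if zero else float(ops.distances_mm.mean()),
        max_distance_mm=0.0 if zero else float(ops.distances_mm.max()),
        I_r_mm4=radial_moment(ops),
        zero_invasion=zero,
        n_ray_fallback=int(ops.fallback_flags.sum()),
    )


def export_polar_data(ops: OuterPixelSet, path: str | Path) -> None:
    """Write per-pixel polar data (x_px, y_px, distance_mm, angle_deg) as CSV."""
    df = pd.DataFrame(
        {
            "x_px": ops.points[:, 0],
            "y_px": ops.points[:, 1],
            "distance_mm": ops.distances_mm,
            "angle_deg": ops.angles_deg,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def plot_polar(ops: OuterPixelSet, ax=None, principal_angles_deg=None, **scatter_kw):
    """Polar scatter of outer-pixel distance vs angle.

    The initial boundary is the plot centre (r = 0). Optionally draws
    the principal invasion axes. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    scatter_kw.setdefault("s", 2)
    ax.scatter(np.radians(ops.angles_deg), ops.distances_mm, **scatter_kw)
    if principal_angles_deg is not None and len(ops):
        rmax = float(ops.distances_mm.max())
        for ang, color in zip(principal_angles_deg, ("tab:blue", "black")):
            for a in (ang, ang + 180.0):
                ax.plot([np.radians(a)] * 2, [0, rmax], color=color, lw=1)
    ax.set_xlabel("angle (deg)")
    return ax
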