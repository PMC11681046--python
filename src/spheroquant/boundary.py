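"""Initial-spheroid boundary segmentation and centroid alignment.

The Day-0 spheroid silhouette is closed morphologically (nuclear
staining leaves gaps), hole-filled, reduced to its largest 8-connected
component, and its outer contour traced at the 0.5 iso-level into an
ordered simple polygon. That polygon, translated onto the Day-2 frame by
centroid overlap (translation only, never rotation or scale), is the
reference against which all invasion distances are measured.

Coordinates are image-frame throughout: x = column, y = row, 0-based,
pixel centres at integers, y increasing downward.

Radial distance for an exterior point p follows the ray from the Day-0
centroid through p; the distance is measured from p back to the last
boundary crossing along that ray, so for non-convex boundaries it
quantifies penetration beyond the outermost edge crossed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from skimage import measure, morphology

from .binarize import BinaryMask
from .errors import DegenerateSpheroidError, EmptyMaskError

__all__ = [
    "SpheroidBoundary",
    "mask_centroid",
    "segment_boundary",
    "align_boundary",
    "point_in_boundary",
    "ray_boundary_distance",
    "ray_distances",
]

#: Smallest connected component (pixels) accepted as a spheroid.
MIN_SPHEROID_PIXELS = 10


@dataclass
class SpheroidBoundary:
    """Closed simple polygon delimiting the initial spheroid.

    ``centroid`` is the polygon's area centroid (the (x0, y0) reference
    of all angle and ray computations). ``mask_centroid`` is the pixel
    mean of the largest connected component of the source mask; centroid
    alignment between timepoints uses mask centroids so that identical
    masks align with exactly zero translation.
    """

    vertices: np.ndarray  # (N, 2) float, columns (x, y)
    centroid: tuple[float, float]
    pixel_size_um: float
    source_id: str = ""
    mask_centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("boundary needs >=3 (x, y) vertices")
        if self.mask_centroid is None:
            self.mask_centroid = self.centroid

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "SpheroidBoundary":
        return SpheroidBoundary(
            vertices=self.vertices + np.array([dx, dy]),
            centroid=(self.centroid[0] + dx, self.centroid[1] + dy),
            pixel_size_um=self.pixel_size_um,
            source_id=self.source_id,
            mask_centroid=(self.mask_centroid[0] + dx, self.mask_centroid[1] + dy),
        )

    def export(self, csv_path: str | Path, json_path: str | Path | None = None,
               translation: tuple[float, float] = (0.0, 0.0)) -> None:
        """Write vertices as CSV (x_px, y_px) plus a JSON audit sidecar."""
        lines = ["x_px,y_px"] + [f"{x:.6f},{y:.6f}" for x, y in self.vertices]
        Path(csv_path).write_text("\n".join(lines) + "\n")
        if json_path is not None:
            Path(json_path).write_text(json.dumps({
                "source_id": self.source_id,
                "centroid_px": list(self.centroid),
                "mask_centroid_px": list(self.mask_centroid),
                "translation_applied_px": list(translation),
                "pixel_size_um": self.pixel_size_um,
                "n_vertices": int(len(self.vertices)),
            }, indent=2, sort_keys=True) + "\n")


def mask_centroid(mask: BinaryMask) -> tuple[float, float]:
    """Unweighted mean (x, y) of foreground pixel centres."""
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise EmptyMaskError("cannot compute the centroid of an empty mask")
    return float(cols.mean()), float(rows.mean())


def _largest_component(pixels: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptyMaskError("mask has no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def segment_boundary(
    day0_mask: BinaryMask, closing_radius_px: int = 5
) -> SpheroidBoundary:
    """Trace the initial spheroid edge as an ordered closed polygon.

    Steps: morphological closing (disk, default radius 5 px) then hole
    filling; keep the largest 8-connected component; trace its outer
    contour at the 0.5 iso-level; take the polygon's area centroid as
    the (x0, y0) reference.
    """
    if day0_mask.foreground_count == 0:
        raise EmptyMaskError("cannot segment a boundary from an empty mask")
    work = day0_mask.pixels
    if closing_radius_px > 0:
        work = morphology.closing(work, morphology.disk(closing_radius_px))
    work = ndimage.binary_fill_holes(work)
    comp = _largest_component(work)
    if int(comp.sum()) < MIN_SPHEROID_PIXELS:
        raise DegenerateSpheroidError(
            f"largest component has {int(comp.sum())} px (< {MIN_SPHEROID_PIXELS})"
        )
    # Pad so components touching the frame still close; contours are in
    # (row, col) order and subpixel via linear interpolation at 0.5.
    padded = np.pad(comp, 1).astype(float)
    contours = measure.find_contours(padded, level=0.5)
    contour = max(contours, key=lambda c: _ring_area(c))
    verts = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])  # (x, y), unpad
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    poly = Polygon(verts)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        verts = np.asarray(poly.exterior.coords)[:-1]
    c = poly.centroid
    raw_comp_centroid = _largest_component(day0_mask.pixels)
    rows, cols = np.nonzero(raw_comp_centroid)
    return SpheroidBoundary(
        vertices=verts,
        centroid=(float(c.x), float(c.y)),
        pixel_size_um=day0_mask.pixel_size_um,
        source_id=day0_mask.id,
        mask_centroid=(float(cols.mean()), float(rows.mean())),
    )


def _ring_area(contour_rc: np.ndarray) -> float:
    """Shoelace area of a closed (row, col) contour."""
    y, x = contour_rc[:, 0], contour_rc[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def align_boundary(boundary: SpheroidBoundary, day2_mask: BinaryMask) -> SpheroidBoundary:
    """Translate the Day-0 boundary onto the Day-2 frame by centroid overlap.

    The Day-2 reference centroid is the pixel mean of the *largest
    connected component* of the Day-2 mask (the spheroid bulk), so that
    scattered invading nuclei do not bias the alignment. Rotation and
    scaling are never applied.
    """
    if day2_mask.foreground_count == 0:
        raise EmptyMaskError("cannot align to an empty Day-2 mask")
    bulk = _largest_component(day2_mask.pixels)
    rows, cols = np.nonzero(bulk)
    cx2, cy2 = float(cols.mean()), float(rows.mean())
    dx = cx2 - boundary.mask_centroid[0]
    dy = cy2 - boundary.mask_centroid[1]
    return boundary.translated(dx, dy)


def point_in_boundary(boundary: SpheroidBoundary, p: tuple[float, float]) -> bool:
    """Even-odd point-in-polygon; points exactly on an edge count as inside."""
    return bool(shapely.intersects(boundary.polygon, Point(p)))


def ray_boundary_distance(
    boundary: SpheroidBoundary, p: tuple[float, float]
) -> tuple[float, tuple[float, float], bool]:
    """Radial distance from an exterior point back to the boundary.

    Casts the ray from the boundary centroid (x0, y0) through ``p``,
    takes the last crossing of the polygon before ``p``, and returns
    ``(d, hit, fallback)`` where ``d = |p - hit|``. If no crossing is
    found (numerically degenerate geometry) the minimum distance from
    ``p`` to the polygon ring is used and ``fallback`` is True.
    """
    d, hits, flags = ray_distances(boundary, np.asarray([p], dtype=float))
    return float(d[0]), (float(hits[0, 0]), float(hits[0, 1])), bool(flags[0])


def ray_distances(
    boundary: SpheroidBoundary, points: np.ndarray, chunk: int = 4096
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`ray_boundary_distance` for an (N, 2) point array.

    Returns ``(distances, hit_points, fallback_flags)`` in pixel units.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return (np.empty(0), np.empty((0, 2)), np.empty(0, dtype=bool))
    c = np.asarray(boundary.centroid, dtype=float)
    A = boundary.vertices
    B = np.roll(A, -1, axis=0)
    e = B - A  # (E, 2) edge vectors
    w = A - c  # (E, 2) centroid -> edge start
    dists = np.empty(len(pts))
    hits = np.empty((len(pts), 2))
    flags = np.zeros(len(pts), dtype=bool)
    ring = LineString(np.vstack([A, A[:1]]))
    eps = 1e-12
    for start in range(0, len(pts), chunk):
        P = pts[start : start + chunk]
        u = P - c  # (n, 2) ray directions; t=1 at the point itself
        # Solve c + t*u = A + s*e per (point, edge) via 2D cross products.
        denom = u[:, 0:1] * e[:, 1] - u[:, 1:2] * e[:, 0]  # (n, E)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
            s = (w[:, 0] * u[:, 1:2] - w[:, 1] * u[:, 0:1]) / denom
        valid = (
            (np.abs(denom) > eps)
            & (s >= -1e-9)
            & (s <= 1 + 1e-9)
            & (t > eps)
            & (t <= 1 + 1e-9)
        )
        t_masked = np.where(valid, t, -np.inf)
        t_best = t_masked.max(axis=1)
        found = np.isfinite(t_best)
        t_hit = np.clip(t_best, None, 1.0)
        hit = c + t_hit[:, None] * u
        d = np.linalg.norm(P - hit, axis=1)
        # fallback: nearest point on the ring
        for i in np.nonzero(~found)[0]:
            pt = Point(P[i])
            d[i] = ring.distance(pt)
            near = ring.interpolate(ring.project(pt))
            hit[i] = (near.x, near.y)
        dists[start : start + chunk] = d
        hits[start : start + chunk] = hit
        flags[start : start + chunk] = ~found
    return dists, hits, flags
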