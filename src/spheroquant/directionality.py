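"""Directional (anisotropic) invasion analysis.

The second moment of the outer-pixel area can be taken about any axis
through a centre point: with coordinates (x', y') rotated so x' lies
along the axis,

    I_x' = Σ y'² dA        (moment about the x' axis)
    I_y' = Σ x'² dA        (moment about the y' axis)

Principal component analysis of the outer-pixel coordinates gives the
directions of maximum and minimum invasion; the moments and the mean
absolute coordinates along those two axes, and their max/min fold
changes, quantify how directional the invasion is (fold ≈ 1 for
isotropic spread, ≫ 1 under a guidance cue such as matrix tension
toward a stiff post).

Outputs are labelled by meaning: ``I_max_mm4`` is the spread *along*
the maximum-invasion axis (Σ x'² dA with x' on that axis, i.e. the
moment about the perpendicular), so ``I_max >= I_min`` always.
Coordinates are centred on the mean of the outer pixels by default; the
Day-0 centroid may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InsufficientDataError
from .metrics import OuterPixelSet, MM_PER_UM

__all__ = [
    "DirectionalityResult",
    "directional_moments",
    "pca_principal_angles",
    "analyze_directionality",
]

#: Eigenvalue ratio below which the pixel cloud is reported as isotropic.
ISOTROPY_EIGENRATIO = 1.05


@dataclass
class DirectionalityResult:
    """Principal invasion directions and the metrics along them."""

    center_used: tuple[float, float]  # pixel coordinates
    angle_max_deg: float
    angle_min_deg: float
    I_max_mm4: float
    I_min_mm4: float
    mean_dist_max_mm: float
    mean_dist_min_mm: float
    moment_fold_change: float
    distance_fold_change: float
    isotropic: bool = False
    degenerate_minor_axis: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["center_used"] = list(self.center_used)
        return d


def _wrap_axis_angle(deg: float) -> float:
    """Map an axis orientation into [-90, 90)."""
    deg = (deg + 90.0) % 180.0 - 90.0
    return float(deg)


def directional_moments(
    ops: OuterPixelSet, axis_angle_deg: float, center: tuple[float, float]
) -> tuple[float, float]:
    """Second moments (I_x', I_y') about axes rotated by ``axis_angle_deg``.

    Pixel coordinates relative to ``center`` (pixels) are rotated by
    −axis_angle so x' lies along the requested axis; returns
    (Σ y'² dA, Σ x'² dA) in mm⁴. Empty set returns (0, 0).
    """
    if len(ops) == 0:
        return 0.0, 0.0
    s_mm = ops.pixel_size_um * MM_PER_UM
    rel = (ops.points - np.asarray(center, dtype=float)) * s_mm
    a = np.radians(axis_angle_deg)
    x_p = np.cos(a) * rel[:, 0] + np.sin(a) * rel[:, 1]
    y_p = -np.sin(a) * rel[:, 0] + np.cos(a) * rel[:, 1]
    I_x = float(np.sum(y_p**2) * ops.dA_mm2)
    I_y = float(np.sum(x_p**2) * ops.dA_mm2)
    return I_x, I_y


def pca_principal_angles(
    ops: OuterPixelSet,
) -> tuple[float, float, tuple[float, float], bool]:
    """Directions of maximum and minimum invasion from coordinate PCA.

    Returns ``(angle_max_deg, angle_min_deg, center, isotropic)``.
    The centre is the mean of the outer-pixel coordinates; angles are
    axis orientations in [−90, 90) (image frame, y down). If the two
    covariance eigenvalues are nearly equal the orientation is
    meaningless: angle 0 is returned with the isotropy flag set.
    """
    if len(ops) < 2:
        raise InsufficientDataError("PCA needs at least 2 outer pixels")
    pts = ops.points
    center = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    cov = np.cov(pts[:, 0], pts[:, 1], bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if lam_max <= 1e-12:
        raise InsufficientDataError("outer pixels are coincident; no orientation")
    isotropic = lam_min > 0 and (lam_max / lam_min) < ISOTROPY_EIGENRATIO
    if lam_max - lam_min < 1e-12:
        return 0.0, -90.0, center, True
    v = evecs[:, 1]  # max-eigenvalue direction
    angle_max = _wrap_axis_angle(np.degrees(np.arctan2(v[1], v[0])))
    angle_min = _wrap_axis_angle(angle_max + 90.0)
    return angle_max, angle_min, center, bool(isotropic)


def analyze_directionality(
    ops: OuterPixelSet, center: tuple[float, float] | None = None
) -> DirectionalityResult:
    """Full directionality summary at the principal angles.

    ``center`` defaults to the mean outer-pixel coordinate (the PCA
    centre); pass the Day-0 centroid to centre there instead. Mean
    principal-direction distances are the mean absolute transformed
    coordinates. Fold changes are max/min ratios and are ≥ 1; a cloud
    collapsed onto a line yields an infinite moment fold change with
    the ``degenerate_minor_axis`` flag set rather than an error.
    """
    angle_max, angle_min, pca_center, isotropic = pca_principal_angles(ops)
    if center is None:
        center = pca_center
    # x' along the maximum-invasion axis: I_y' = Σ x'² dA is the spread
    # along that axis; with the orthogonal axis it forms the (I_max, I_min) pair.
    I_about_max_axis, I_along_max = directional_moments(ops, angle_max, center)
    I_max = I_along_max
    I_min = I_about_max_axis
    if I_max < I_min:  # guard: PCA orientation vs moment ordering edge cases
        I_max, I_min = I_min, I_max
        angle_max, angle_min = angle_min, angle_max
    s_mm = ops.pixel_size_um * MM_PER_UM
    rel = (ops.points - np.asarray(center, dtype=float)) * s_mm
    a = np.radians(angle_max)
    x_p = np.cos(a) * rel[:, 0] + np.sin(a) * rel[:, 1]
    y_p = -np.sin(a) * rel[:, 0] + np.cos(a) * rel[:, 1]
    mean_max = float(np.abs(x_p).mean())
    mean_min = float(np.abs(y_p).mean())
    degenerate = I_min <= 1e-300 or mean_min <= 1e-300
    return DirectionalityResult(
        center_used=(float(center[0]), float(center[1])),
        angle_max_deg=angle_max,
        angle_min_deg=angle_min,
        I_max_mm4=I_max,
        I_min_mm4=I_min,
        mean_dist_max_mm=mean_max,
        mean_dist_min_mm=mean_min,
        moment_fold_change=float(I_max / I_min) if I_min > 0 else float("inf"),
        distance_fold_change=float(mean_max / mean_min) if mean_min > 0 else float("inf"),
        isotropic=isotropic,
        degenerate_minor_axis=degenerate,
    )
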