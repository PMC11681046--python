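"""End-to-end per-spheroid quantification built from the module layers."""

from __future__ import annotations

from .binarize import BinaryMask
from .boundary import align_boundary, segment_boundary
from .directionality import analyze_directionality
from .errors import InsufficientDataError
from .metrics import OuterPixelSet, find_outer_pixels, summarize_invasion

__all__ = ["quantify_pair"]


def quantify_pair(
    day0_mask: BinaryMask,
    day2_mask: BinaryMask,
    directionality: bool = True,
    closing_radius_px: int = 5,
) -> dict:
    """Quantify one binarized Day-0/Day-2 pair.

    Segments the Day-0 boundary, aligns it to the Day-2 bulk by centroid
    overlap, finds the outer pixels and assembles invasion (and
    optionally directionality) metrics. Returns a flat record dict plus
    the intermediate objects under ``_boundary`` / ``_outer_pixels`` for
    callers that want them (those keys are stripped before export).
    """
    boundary = segment_boundary(day0_mask, closing_radius_px=closing_radius_px)
    aligned = align_boundary(boundary, day2_mask)
    ops = find_outer_pixels(day2_mask, aligned)
    inv = summarize_invasion(day0_mask, day2_mask, aligned, ops)
    record: dict = {"sample_id": day0_mask.id or boundary.source_id}
    record.update(inv.as_dict())
    if directionality:
        try:
            res = analyze_directionality(ops)
            d = res.as_dict()
            record.update(
                {
                    "pca_angle_max_deg": d["angle_max_deg"],
                    "pca_angle_min_deg": d["angle_min_deg"],
                    "I_max_mm4": d["I_max_mm4"],
                    "I_min_mm4": d["I_min_mm4"],
                    "mean_dist_max_mm": d["mean_dist_max_mm"],
                    "mean_dist_min_mm": d["mean_dist_min_mm"],
                    "moment_fold_change": d["moment_fold_change"],
                    "distance_fold_change": d["distance_fold_change"],
                    "pca_isotropic": d["isotropic"],
                }
            )
        except InsufficientDataError:
            record["pca_isotropic"] = None
    record["_boundary"] = aligned
    record["_outer_pixels"] = ops
    return record
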