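import numpy as np
import pandas as pd
import pytest

from oracles import quadrant_angle_oracle

from spheroquant import (
    Annulus,
    BinaryMask,
    Disk,
    FixtureSpec,
    OuterPixelSet,
    area_change,
    export_polar_data,
    find_outer_pixels,
    generate_pair,
    pixel_angle,
    radial_moment,
    segment_boundary,
    summarize_invasion,
)
from spheroquant.boundary import align_boundary
from spheroquant.errors import DimensionError, UndefinedAngleError
from spheroquant.pipeline import quantify_pair


def mask_from(pixels, ps=1.0):
    return BinaryMask(np.asarray(pixels, dtype=bool), ps)


class TestFindOuterPixels:
    def test_no_invasion_gives_empty_set(self, disk_mask):
        b = align_boundary(segment_boundary(disk_mask), disk_mask)
        ops = find_outer_pixels(disk_mask, b)
        assert len(ops) == 0

    def test_single_far_pixel(self, single_pixel_fixture):
        day0, day2, truth = single_pixel_fixture
        b = align_boundary(segment_boundary(day0), day2)
        ops = find_outer_pixels(day2, b)
        assert len(ops) == 1
        assert ops.distances_px[0] == pytest.approx(30.0, abs=0.5)

    def test_annulus_counts_and_mean_distance(self, annulus_fixture):
        day0, day2, truth = annulus_fixture
        b = align_boundary(segment_boundary(day0), day2)
        ops = find_outer_pixels(day2, b)
        assert len(ops) == truth["n_outer_pixels"]
        assert ops.distances_px.mean() == pytest.approx(
            truth["mean_distance_px_continuum"], rel=0.03
        )

    def test_all_points_outside_boundary(self, annulus_fixture):
        day0, day2, _ = annulus_fixture
        b = align_boundary(segment_boundary(day0), day2)
        ops = find_outer_pixels(day2, b)
        from spheroquant import point_in_boundary

        rng = np.random.default_rng(0)
        for i in rng.choice(len(ops), 50, replace=False):
            assert not point_in_boundary(b, tuple(ops.points[i])) or \
                ops.distances_px[i] < 1e-6


class TestPixelAngle:
    @pytest.mark.parametrize(
        "offset,expected",
        [((1, 0), 0.0), ((0, 1), 90.0), ((-1, 0), -180.0), ((0, -1), -90.0)],
    )
    def test_cardinal_directions(self, offset, expected):
        c = (10.0, 20.0)
        assert pixel_angle((c[0] + offset[0], c[1] + offset[1]), c) == pytest.approx(expected)

    def test_circle_matches_quadrant_oracle(self):
        c = (0.0, 0.0)
        for k in range(360):
            a = 2 * np.pi * k / 360 + 0.001
            p = (np.cos(a), np.sin(a))
            assert pixel_angle(p, c) == pytest.approx(
                quadrant_angle_oracle(p, c), abs=1e-9
            )

    def test_centroid_coincidence_error(self):
        with pytest.raises(UndefinedAngleError):
            pixel_angle((3.0, 3.0), (3.0, 3.0))


class TestAreaChange:
    def test_identical_masks_zero(self, disk_mask):
        a0, a2, delta = area_change(disk_mask, disk_mask)
        assert delta == 0.0 and a0 == a2

    def test_hundred_extra_pixels(self):
        m0 = np.zeros((50, 50), bool)
        m0[20:25, 20:25] = True
        m2 = m0.copy()
        m2.flat[np.flatnonzero(~m0.ravel())[:100]] = True
        _, _, delta = area_change(mask_from(m0), mask_from(m2))
        assert delta == pytest.approx(100 * (1e-3) ** 2)  # 1 um pixels -> 1e-4 mm2

    def test_random_pair_matches_counting_loop(self):
        rng = np.random.default_rng(21)
        m0 = rng.random((15, 15)) > 0.6
        m2 = rng.random((15, 15)) > 0.4
        a0, a2, delta = area_change(mask_from(m0), mask_from(m2))
        c0 = sum(bool(v) for v in m0.ravel())
        c2 = sum(bool(v) for v in m2.ravel())
        assert a0 == pytest.approx(c0 * 1e-6) and a2 == pytest.approx(c2 * 1e-6)
        assert delta == pytest.approx((c2 - c0) * 1e-6)

    def test_negative_delta_warns(self, disk_mask):
        smaller = disk_mask.pixels.copy()
        smaller[80, :] = False
        with pytest.warns(UserWarning, match="negative area change"):
            area_change(disk_mask, mask_from(smaller))

    def test_shape_mismatch(self, disk_mask):
        with pytest.raises(DimensionError):
            area_change(disk_mask, mask_from(np.zeros((10, 10), bool)))


def pixelset(points, d_px, ps_um=1.0):
    s = ps_um * 1e-3
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    d = np.asarray(d_px, dtype=float)
    ang = np.zeros(len(pts))
    return OuterPixelSet(pts, d * s, ang, s**2, ps_um)


class TestRadialMoment:
    def test_empty_zero(self):
        assert radial_moment(pixelset(np.empty((0, 2)), [])) == 0.0

    def test_single_pixel_closed_form(self):
        # d = 10 px at 1 um/px: I_r = 100 um^4 = 1e-10 mm^4
        assert radial_moment(pixelset([(0, 0)], [10.0])) == pytest.approx(1e-10)

    def test_annulus_closed_form(self, annulus_fixture):
        day0, day2, truth = annulus_fixture
        rec = quantify_pair(day0, day2, directionality=False)
        I_r_px4 = rec["I_r_mm4"] / (1e-3) ** 4
        assert I_r_px4 == pytest.approx(truth["I_r_px4_continuum"], rel=0.03)


class TestSummarizeInvasion:
    def test_zero_invasion_flag(self, disk_mask):
        b = align_boundary(segment_boundary(disk_mask), disk_mask)
        ops = find_outer_pixels(disk_mask, b)
        inv = summarize_invasion(disk_mask, disk_mask, b, ops)
        assert inv.zero_invasion
        assert inv.mean_distance_mm == inv.max_distance_mm == inv.I_r_mm4 == 0.0
        assert inv.area_day0_mm2 > 0

    def test_annulus_all_fields(self, annulus_fixture):
        day0, day2, truth = annulus_fixture
        b = align_boundary(segment_boundary(day0), day2)
        ops = find_outer_pixels(day2, b)
        inv = summarize_invasion(day0, day2, b, ops)
        assert inv.n_outer_pixels == truth["n_outer_pixels"]
        assert inv.outer_area_mm2 == inv.n_outer_pixels * ops.dA_mm2
        assert inv.delta_area_mm2 == pytest.approx(truth["delta_area_mm2"])
        assert inv.mean_distance_mm * 1e3 == pytest.approx(
            truth["mean_distance_px_continuum"], rel=0.03
        )
        assert inv.max_distance_mm >= inv.mean_distance_mm

    def test_equal_moment_different_area_and_distance(self):
        """Dense/near vs sparse/far pixel sets: same I_r, distinguishable ΔA, D̄."""
        dense = pixelset([(i, 0) for i in range(400)], np.full(400, 5.0))
        # 100 pixels at d = 10: sum d^2 = 100*100 = 10000 = 400*25
        sparse = pixelset([(i, 1) for i in range(100)], np.full(100, 10.0))
        assert radial_moment(dense) == pytest.approx(radial_moment(sparse), rel=0.02)
        assert len(dense) != len(sparse)
        assert dense.distances_mm.mean() != sparse.distances_mm.mean()


class TestExportPolar:
    def test_empty_header_only(self, tmp_path):
        p = tmp_path / "polar.csv"
        export_polar_data(pixelset(np.empty((0, 2)), []), p)
        assert p.read_text().strip() == "x_px,y_px,distance_mm,angle_deg"

    def test_cardinal_angles(self, tmp_path):
        s = 1e-3
        ops = OuterPixelSet(
            [(1, 0), (0, 1), (-1, 0), (0, -1)],
            np.full(4, s),
            np.array([0.0, 90.0, 180.0 - 360.0, -90.0]),
            s**2,
            1.0,
        )
        p = tmp_path / "polar.csv"
        export_polar_data(ops, p)
        df = pd.read_csv(p)
        assert sorted(df["angle_deg"]) == [-180.0, -90.0, 0.0, 90.0]

    def test_roundtrip(self, tmp_path, annulus_fixture):
        day0, day2, _ = annulus_fixture
        rec = quantify_pair(day0, day2, directionality=False)
        ops = rec["_outer_pixels"]
        p = tmp_path / "polar.csv"
        export_polar_data(ops, p)
        df = pd.read_csv(p)
        np.testing.assert_allclose(df["distance_mm"], ops.distances_mm, rtol=1e-9)
        np.testing.assert_allclose(df["angle_deg"], ops.angles_deg, rtol=1e-9)


class TestInvariances:
    def test_pixel_size_scaling_laws(self, annulus_fixture):
        day0, day2, _ = annulus_fixture
        rec1 = quantify_pair(day0, day2, directionality=False)
        day0s = BinaryMask(day0.pixels, 2.0, id=day0.id)
        day2s = BinaryMask(day2.pixels, 2.0, id=day2.id)
        rec2 = quantify_pair(day0s, day2s, directionality=False)
        assert rec2["delta_area_mm2"] == pytest.approx(4 * rec1["delta_area_mm2"], rel=1e-12)
        assert rec2["mean_distance_mm"] == pytest.approx(2 * rec1["mean_distance_mm"], rel=1e-9)
        assert rec2["I_r_mm4"] == pytest.approx(16 * rec1["I_r_mm4"], rel=1e-9)

    def test_rotation_90_robustness(self, annulus_fixture):
        day0, day2, _ = annulus_fixture
        rec1 = quantify_pair(day0, day2, directionality=False)
        r0 = BinaryMask(np.rot90(day0.pixels), 1.0, id=day0.id)
        r2 = BinaryMask(np.rot90(day2.pixels), 1.0, id=day2.id)
        rec2 = quantify_pair(r0, r2, directionality=False)
        assert rec2["delta_area_mm2"] == rec1["delta_area_mm2"]
        assert rec2["n_outer_pixels"] == rec1["n_outer_pixels"]
        assert rec2["mean_distance_mm"] == pytest.approx(rec1["mean_distance_mm"], rel=0.01)
        assert rec2["I_r_mm4"] == pytest.approx(rec1["I_r_mm4"], rel=0.01)

    def test_translation_leaves_metrics_unchanged(self, annulus_fixture):
        day0, day2, _ = annulus_fixture
        rec1 = quantify_pair(day0, day2, directionality=False)
        t0 = BinaryMask(np.roll(np.roll(day0.pixels, 6, 0), -9, 1), 1.0, id=day0.id)
        t2 = BinaryMask(np.roll(np.roll(day2.pixels, 6, 0), -9, 1), 1.0, id=day2.id)
        rec2 = quantify_pair(t0, t2, directionality=False)
        assert rec2["n_outer_pixels"] == rec1["n_outer_pixels"]
        assert rec2["mean_distance_mm"] == pytest.approx(rec1["mean_distance_mm"], rel=1e-9)
        assert rec2["I_r_mm4"] == pytest.approx(rec1["I_r_mm4"], rel=1e-9)
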