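"""Geometric measurement operators against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from spinegrader import geometry
from spinegrader.datamodel import LabelMap
from spinegrader.geometry import (
    Contour,
    EmptyMaskError,
    GeometryError,
    contact,
    disc_excess,
    expected_root_position,
    extract_contour,
    posterior_tangent_construction,
    project_vertebral_footprint,
    region_area,
)


def _disk(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rect_contour(x0, y0, w, h, n=50):
    """Dense analytic rectangle contour (x grows posterior, y inferior)."""
    t = np.linspace(0, 1, n, endpoint=False)
    top = np.column_stack([x0 + w * t, np.full(n, y0)])
    right = np.column_stack([np.full(n, x0 + w), y0 + h * t])
    bottom = np.column_stack([x0 + w * (1 - t), np.full(n, y0 + h)])
    left = np.column_stack([np.full(n, x0), y0 + h * (1 - t)])
    return Contour(np.vstack([top, right, bottom, left]))


class TestExtractContour:
    def test_solid_square_area(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10 px at 1 mm
        c = extract_contour(mask, (1.0, 1.0))
        assert c.area == pytest.approx(100.0, rel=0.03)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert extract_contour(mask, (1.0, 1.0)).area <= 1.0

    def test_circle_perimeter(self):
        mask = _disk((50, 50), (25, 25), 20)
        c = extract_contour(mask, (1.0, 1.0))
        assert c.perimeter == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_contour(np.zeros((5, 5), dtype=bool), (1.0, 1.0))

    def test_multiple_components_takes_largest(self, caplog):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:12, 2:12] = True
        mask[15, 15] = True
        with caplog.at_level("WARNING"):
            c = extract_contour(mask, (1.0, 1.0))
        assert c.area == pytest.approx(100.0, rel=0.05)
        assert "components" in caplog.text

    def test_winding_normalized_ccw(self):
        c = Contour([(0, 0), (0, 4), (4, 4), (4, 0)])  # given clockwise
        assert c.area > 0


class TestProjection:
    def _lm(self, px, spacing=(1.0, 1.0)):
        return LabelMap(px.astype(int), "axial", spacing, segment_id="L4/L5")

    def test_identity(self):
        m = _disk((32, 32), (16, 16), 8)
        lm = self._lm(m)
        proj = project_vertebral_footprint(lm, lm, lm, 1)
        assert np.array_equal(proj, m)

    def test_shifted_masks_union(self):
        upper = _disk((32, 32), (14, 16), 8)
        lower = _disk((32, 32), (18, 16), 8)
        proj = project_vertebral_footprint(
            self._lm(upper), self._lm(lower), self._lm(np.zeros((32, 32))), 1
        )
        assert np.array_equal(proj, upper | lower)
        assert proj.sum() >= max(upper.sum(), lower.sum())

    def test_spacing_mismatch_resamples_in_mm(self):
        # source at 0.5 mm/px, target at 1.0 mm/px: brute-force mm lookup
        src = _disk((64, 64), (32, 32), 20)
        src_lm = self._lm(src, spacing=(0.5, 0.5))
        tgt_lm = self._lm(np.zeros((32, 32)), spacing=(1.0, 1.0))
        proj = project_vertebral_footprint(src_lm, src_lm, tgt_lm, 1)
        expected = np.zeros((32, 32), dtype=bool)
        for r in range(32):
            for c in range(32):
                ri, ci = round(r * 1.0 / 0.5), round(c * 1.0 / 0.5)
                if 0 <= ri < 64 and 0 <= ci < 64:
                    expected[r, c] = src[ri, ci]
        assert np.array_equal(proj, expected)

    def test_empty_projection_raises(self):
        empty = self._lm(np.zeros((8, 8)))
        with pytest.raises(EmptyMaskError):
            project_vertebral_footprint(empty, empty, empty, 1)


class TestRegionArea:
    def test_pixel_count_times_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True
        assert region_area(mask, (1.0, 1.0)) == 100.0
        assert region_area(np.zeros((4, 4), dtype=bool), (1.0, 1.0)) == 0.0

    @pytest.mark.parametrize("spacing,rel", [(1.0, 0.08), (0.5, 0.04), (0.25, 0.02)])
    def test_ellipse_area_converges_with_resolution(self, spacing, rel):
        # semi-axes 8 x 4 mm -> analytic area pi*8*4 = 100.53 mm^2
        n = int(24 / spacing)
        rows = np.arange(n)[:, None] * spacing - 12
        cols = np.arange(n)[None, :] * spacing - 12
        mask = (cols / 8.0) ** 2 + (rows / 4.0) ** 2 <= 1.0
        assert region_area(mask, (spacing, spacing)) == pytest.approx(
            np.pi * 8 * 4, rel=rel
        )


class TestDiscExcess:
    def test_disc_inside_footprint_is_empty(self):
        fp = _disk((40, 40), (20, 20), 15)
        disc = _disk((40, 40), (20, 20), 12)
        assert disc_excess(disc, fp, (1.0, 1.0)) == []

    def test_posterior_bump_depth_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(32, 64))
            fp = _disk((n, n), (n // 2, n // 2), n // 4)
            disc = fp | _disk(
                (n, n),
                (n // 2 + n // 4, n // 2 + int(rng.integers(-4, 5))),
                int(rng.integers(2, 6)),
            )
            regions = disc_excess(disc, fp, (1.0, 1.0))
            if not regions:
                continue
            ex = disc & ~fp
            ex_pts = np.argwhere(ex)
            fp_pts = np.argwhere(fp)
            brute = cdist(ex_pts, fp_pts).min(axis=1).max()
            assert max(r.max_excess_mm for r in regions) == pytest.approx(brute)

    def test_anterior_excess_ignored(self):
        fp = _disk((40, 40), (20, 20), 10)
        disc = fp | _disk((40, 40), (6, 20), 4)  # anterior blob (small row)
        assert disc_excess(disc, fp, (1.0, 1.0)) == []

    def test_angular_fraction_of_half_ring(self):
        # uniform 4 px rim expansion over the posterior half
        rr, cc = np.mgrid[:80, :80]
        rho = np.hypot(rr - 40, cc - 40)
        fp = rho <= 20
        disc = fp | ((rho <= 24) & (rr >= 40))
        regions = disc_excess(disc, fp, (1.0, 1.0))
        assert len(regions) == 1
        assert regions[0].max_excess_mm == pytest.approx(4.0, abs=0.5)
        assert regions[0].angular_span_fraction == pytest.approx(0.5, abs=0.04)

    def test_outputs_scale_linearly_with_spacing(self):
        fp = _disk((60, 60), (30, 30), 15)
        disc = fp | _disk((60, 60), (47, 30), 5)
        r1 = disc_excess(disc, fp, (1.0, 1.0))[0]
        r2 = disc_excess(disc, fp, (2.0, 2.0))[0]
        assert r2.max_excess_mm == pytest.approx(2 * r1.max_excess_mm)
        assert r2.dome_width_mm == pytest.approx(2 * r1.dome_width_mm, rel=0.01)
        assert r2.base_width_mm == pytest.approx(2 * r1.base_width_mm, rel=0.05)
        assert r2.angular_span_fraction == pytest.approx(
            r1.angular_span_fraction, abs=0.01
        )

    def test_ap_axis_mode_measures_along_rows(self):
        # 5 px bump straight posterior: both metrics agree there
        fp = np.zeros((40, 40), dtype=bool)
        fp[10:20, 10:30] = True
        disc = fp.copy()
        disc[20:25, 18:22] = True
        r_perp = disc_excess(disc, fp, (1.0, 1.0))[0]
        r_ap = disc_excess(disc, fp, (1.0, 1.0), ap_axis_only=True)[0]
        assert r_ap.max_excess_mm == pytest.approx(5.0)
        assert r_perp.max_excess_mm == pytest.approx(5.0)


class TestTangentConstruction:
    def test_aligned_rectangles_zero_offset(self):
        upper = _rect_contour(10, 0, 30, 24)
        lower = _rect_contour(10, 32, 30, 24)
        tc = posterior_tangent_construction(upper, lower)
        assert tc.offset_mm == pytest.approx(0.0, abs=1e-9)
        assert tc.endplate_length_mm == pytest.approx(30.0, rel=0.02)

    @pytest.mark.parametrize("shift,ratio", [(6.0, 20.0), (12.0, 40.0)])
    def test_anterior_shift_gives_exact_ratio(self, shift, ratio):
        upper = _rect_contour(10 - shift, 0, 30, 24)
        lower = _rect_contour(10, 32, 30, 24)
        tc = posterior_tangent_construction(upper, lower)
        assert tc.offset_mm == pytest.approx(shift, abs=0.5)
        assert tc.listhesis_percent == pytest.approx(ratio, abs=1.7)

    @pytest.mark.parametrize("angle_deg", [0.0, 7.0, 15.0])
    def test_ratio_invariant_under_joint_rotation(self, angle_deg):
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        upper = _rect_contour(4, 0, 30, 24)
        lower = _rect_contour(10, 32, 30, 24)
        ref = posterior_tangent_construction(upper, lower).listhesis_percent
        tc = posterior_tangent_construction(
            Contour(upper.points @ rot.T), Contour(lower.points @ rot.T)
        )
        assert tc.listhesis_percent == pytest.approx(ref, abs=1.0)

    def test_degenerate_contour_raises(self):
        with pytest.raises(GeometryError):
            # collinear points cannot form a contour at all
            Contour([(0, 0), (1, 1), (2, 2)])


class TestRootPosition:
    def test_midpoint_and_identity(self):
        assert np.allclose(expected_root_position((0, 0), (2, 2), 0.5), (1, 1))
        assert np.allclose(expected_root_position((3, 4), (9, 9), 0.0), (3, 4))

    def test_missing_neighbor_copies_available(self, caplog):
        with caplog.at_level("WARNING"):
            out = expected_root_position(None, (5, 6), 0.5)
        assert np.allclose(out, (5, 6))

    @given(
        ax=st.floats(-50, 50), ay=st.floats(-50, 50),
        bx=st.floats(-50, 50), by=st.floats(-50, 50),
        f=st.floats(0, 1),
    )
    def test_interpolant_lies_on_segment(self, ax, ay, bx, by, f):
        p = expected_root_position((ax, ay), (bx, by), f)
        a, b = np.array([ax, ay]), np.array([bx, by])
        u, v = b - a, p - a
        cross = u[0] * v[1] - u[1] * v[0]
        assert abs(cross) < 1e-6 * max(1.0, np.linalg.norm(b - a) ** 2)
        assert np.linalg.norm(p - a) <= np.linalg.norm(b - a) + 1e-9


class TestContact:
    def test_touching_separated_overlapping(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[2:5, 2:5] = True
        b[5:8, 5:8] = True  # diagonal touch
        assert contact(a, b)
        b2 = np.zeros_like(b)
        b2[7:9, 7:9] = True  # 2 px gap
        assert not contact(a, b2)
        assert contact(a, a)
        assert not contact(a, np.zeros_like(a))
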