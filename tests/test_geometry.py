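"""Contour geometry: areas, SSA, setup-error norms, rasterization, clipping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordshift import (
    Contour,
    DomainError,
    EmptyRegionError,
    GeometryError,
    RegionPartition,
    ShiftVector,
    Structure,
    clip_external,
    contour_change,
    polygon_area,
    rasterize,
    region_ssa,
    split_by_region,
    three_d_error,
)
from cordshift.geometry import mask_volume_cc, translate_structure

from conftest import circle_contour, square_contour, uniform_grid


class TestPolygonArea:
    def test_unit_square_cm2(self):
        assert polygon_area(square_contour(0.0, 10.0)) == pytest.approx(1.0)

    def test_orientation_independent(self):
        c = square_contour(0.0, 10.0)
        rev = Contour(0.0, tuple(reversed(c.points)))
        assert polygon_area(rev) == pytest.approx(polygon_area(c))

    def test_circle_approximation(self):
        # regular 360-gon, r = 50 mm: area -> pi r^2 = 78.54 cm^2
        c = circle_contour(0.0, 50.0, n=360)
        assert polygon_area(c) == pytest.approx(math.pi * 25.0, rel=1e-3)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            Contour(0.0, ((0, 0), (1, 0)))

    def test_self_intersection_rejected(self):
        bowtie = Contour(0.0, ((0, 0), (10, 10), (10, 0), (0, 10)))
        with pytest.raises(GeometryError):
            polygon_area(bowtie)

    @given(
        shift=st.tuples(
            st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
        ),
        rotate_by=st.integers(0, 11),
        n=st.integers(4, 12),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariance_under_rotation_reversal_translation(
        self, shift, rotate_by, n, seed
    ):
        # star-shaped simple polygons: jittered angles around the origin
        # with every angular gap below pi
        rng = np.random.default_rng(seed)
        angles = (np.arange(n) + rng.uniform(0.1, 0.9, n)) * 2 * np.pi / n
        radii = rng.uniform(5, 30, n)
        pts = [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
        base = Contour(0.0, tuple(pts))
        rolled = Contour(0.0, tuple(pts[rotate_by % n :] + pts[: rotate_by % n]))
        moved = Contour(0.0, tuple((x + shift[0], z + shift[1]) for x, z in pts))
        a = polygon_area(base)
        assert polygon_area(rolled) == pytest.approx(a, rel=1e-12)
        assert polygon_area(moved) == pytest.approx(a, rel=1e-9)


def _external_with_areas(areas_cm2, y0=0.0, dy=2.5):
    contours = [
        square_contour(y0 + i * dy, math.sqrt(a * 100.0))
        for i, a in enumerate(areas_cm2)
    ]
    return Structure("external", tuple(contours), role="external")


class TestRegionSSA:
    @pytest.mark.parametrize(
        "areas, expected",
        [
            ([100.0, 120.0, 140.0], 120.0),
            ([171.4], 171.4),
            ([100.0, 110.0, 130.0, 200.0], 120.0),
        ],
    )
    def test_median_slice_area(self, areas, expected):
        ext = _external_with_areas(areas)
        assert region_ssa(ext, (-1.0, 100.0)) == pytest.approx(expected, rel=1e-9)

    def test_empty_region_errors(self):
        ext = _external_with_areas([100.0])
        with pytest.raises(EmptyRegionError):
            region_ssa(ext, (50.0, 60.0))


class TestContourChange:
    @pytest.mark.parametrize(
        "ct, cbct, expected",
        [
            (100.0, 100.0, 0.0),
            (192.7, 179.8, 0.06694),  # course-end shrink of the upper neck
            (100.0, 110.0, -0.10),  # swelling is negative
        ],
    )
    def test_fractional_change(self, ct, cbct, expected):
        assert contour_change(ct, cbct) == pytest.approx(expected, abs=5e-6)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(DomainError):
            contour_change(0.0, 10.0)


class TestThreeDError:
    @pytest.mark.parametrize(
        "shift, expected",
        [((0, 0, 0), 0.0), ((1, 2, 2), 3.0), ((-8, 0, 0), 8.0)],
    )
    def test_magnitude(self, shift, expected):
        assert three_d_error(ShiftVector(*shift)) == pytest.approx(expected)

    @given(
        v=st.tuples(*[st.floats(-20, 20, allow_nan=False)] * 3),
        w=st.tuples(*[st.floats(-20, 20, allow_nan=False)] * 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_norm_axioms(self, v, w):
        sv, sw = ShiftVector(*v), ShiftVector(*w)
        assert three_d_error(sv) >= 0
        assert three_d_error(-sv) == pytest.approx(three_d_error(sv))
        total = ShiftVector(*(a + b for a, b in zip(v, w)))
        assert three_d_error(total) <= three_d_error(sv) + three_d_error(sw) + 1e-9


class TestRasterize:
    def test_cylinder_volume(self):
        # r = 10 mm, h = 50 mm -> 15.71 cc, within 2% at 1 mm spacing
        contours = tuple(circle_contour(0.5 + i, 10.0) for i in range(50))
        cyl = Structure("cyl", contours)
        grid = uniform_grid(0.0, shape=(30, 50, 30), origin=(-14.5, 0.5, -14.5))
        vol = mask_volume_cc(rasterize(cyl, grid), grid)
        assert vol == pytest.approx(math.pi * 1.0 * 5.0, rel=0.02)

    def test_volume_converges_with_spacing(self):
        contours = tuple(circle_contour(1.0 + 2 * i, 10.0) for i in range(25))
        cyl = Structure("cyl", contours)
        analytic = math.pi * 1.0 * 5.0
        errs = []
        for s in (2.0, 0.5):
            n = int(30 / s)
            grid = uniform_grid(
                0.0,
                shape=(n, int(50 / s), n),
                spacing=(s, s, s),
                origin=(-15 + s / 2, s / 2, -15 + s / 2),
            )
            vol = mask_volume_cc(rasterize(cyl, grid), grid)
            errs.append(abs(vol - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_subvoxel_polygon_between_centers_is_empty(self):
        tiny = Structure("dot", (square_contour(0.5, 0.2, cx=0.0, cz=0.0),))
        grid = uniform_grid(0.0, shape=(4, 1, 4), origin=(-1.5, 0.5, -1.5))
        # voxel centers at +/-0.5, +/-1.5; polygon spans (-0.1, 0.1)
        assert not rasterize(tiny, grid).any()

    def test_full_grid_rectangle_marks_all(self):
        grid = uniform_grid(0.0, shape=(5, 2, 5), origin=(0.0, 0.5, 0.0))
        big = Structure(
            "slab",
            (square_contour(0.5, 100.0, cx=2, cz=2), square_contour(1.5, 100.0, cx=2, cz=2)),
        )
        assert rasterize(big, grid).all()


class TestSplitByRegion:
    def _cord(self, ys):
        return Structure("sc", tuple(circle_contour(y, 4.0, n=16) for y in ys))

    def test_spanning_cord_fills_all_regions(self, simple_partition):
        sc = self._cord(np.arange(1.25, 160, 2.5))
        parts = split_by_region(sc, simple_partition)
        assert all(len(parts[r].contours) > 0 for r in ("C1_C3", "C4_C5", "C6_C7"))
        total = sum(len(p.contours) for p in parts.values())
        assert total == len(sc.contours)

    def test_localized_cord_leaves_other_regions_empty(self, simple_partition):
        sc = self._cord([110.0, 120.0, 130.0])
        parts = split_by_region(sc, simple_partition)
        assert len(parts["C1_C3"].contours) == 3
        assert len(parts["C4_C5"].contours) == 0
        assert len(parts["C6_C7"].contours) == 0

    def test_boundary_slice_goes_to_halfopen_owner(self, simple_partition):
        sc = self._cord([60.0])  # exactly at C4_C5's y_min
        parts = split_by_region(sc, simple_partition)
        assert len(parts["C4_C5"].contours) == 1
        assert len(parts["C6_C7"].contours) == 0

    def test_out_of_window_contours_dropped(self, simple_partition):
        sc = self._cord([-5.0, 30.0, 200.0])
        parts = split_by_region(sc, simple_partition)
        assert sum(len(p.contours) for p in parts.values()) == 1


class TestClipExternal:
    def test_zero_shrink_is_identity(self):
        ext = _external_with_areas([100.0, 120.0])
        assert clip_external(ext, 0.0).contours == ext.contours

    def test_area_scaling(self):
        # 19% shrink of a ~100 cm^2 circle leaves 81% of its area
        ext = Structure("external", (circle_contour(0.0, math.sqrt(10000 / math.pi)),))
        clipped = clip_external(ext, 0.19)
        ratio = polygon_area(clipped.contours[0]) / polygon_area(ext.contours[0])
        assert ratio == pytest.approx(0.81, rel=1e-9)

    def test_course_end_lower_neck_ratio(self, simple_partition):
        # area ratio 140.7/171.4 corresponds to an 17.9% shrink
        r = math.sqrt(171.4 * 100 / math.pi)
        ext = Structure("external", (circle_contour(30.0, r),), role="external")
        clipped = clip_external(ext, {"C6_C7": 0.179}, simple_partition)
        ratio = polygon_area(clipped.contours[0]) / polygon_area(ext.contours[0])
        assert ratio == pytest.approx(140.7 / 171.4, abs=5e-4)

    @pytest.mark.parametrize("f", [0.05, 0.179, 0.5, -0.2])
    def test_ssa_scales_exactly(self, f):
        ext = _external_with_areas([100.0, 120.0, 140.0])
        ssa0 = region_ssa(ext, (-1, 100))
        ssa1 = region_ssa(clip_external(ext, f), (-1, 100))
        assert ssa1 == pytest.approx((1 - f) * ssa0, rel=1e-6)
        assert contour_change(ssa0, ssa1) == pytest.approx(f, abs=1e-9)

    def test_shrink_out_of_domain(self):
        ext = _external_with_areas([100.0])
        with pytest.raises(DomainError):
            clip_external(ext, 1.0)


class TestStructuresAndPartition:
    def test_duplicate_slice_rejected(self):
        with pytest.raises(GeometryError):
            Structure("s", (square_contour(0.0, 10.0), square_contour(0.0, 20.0)))

    def test_contours_sorted_by_slice(self):
        s = Structure("s", (square_contour(5.0, 10.0), square_contour(0.0, 10.0)))
        assert list(s.y_slices) == [0.0, 5.0]

    def test_partition_requires_cord_regions(self):
        with pytest.raises(DomainError):
            RegionPartition({"C1_C3": (0.0, 10.0)})

    def test_partition_rejects_overlap(self):
        with pytest.raises(DomainError):
            RegionPartition(
                {"C1_C3": (0.0, 10.0), "C4_C5": (5.0, 15.0), "C6_C7": (15.0, 20.0)}
            )

    def test_translate_preserves_area(self):
        s = Structure("s", (square_contour(0.0, 10.0),))
        moved = translate_structure(s, ShiftVector(3.0, -2.0, 1.5))
        assert moved.contours[0].y_slice == pytest.approx(-2.0)
        assert polygon_area(moved.contours[0]) == pytest.approx(1.0)
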