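"""Rigid-shift Dmax estimator: identities, continuity and engine agreement."""

import numpy as np
import pytest

from cordshift import (
    DoseGrid,
    OutOfExtentError,
    ShiftVector,
    Structure,
    displace_structure,
    dmax_displaced,
    fit_displaced_vs_setup,
    trigger_replan,
)
from cordshift.estimator import DisplacedEstimate
from cordshift.pipeline import displaced_setup_pairs

from conftest import circle_contour


def cord_structure(ys, r=4.0, cx=0.0, cz=0.0):
    return Structure(
        "sc", tuple(circle_contour(y, r, cx=cx, cz=cz, n=32) for y in ys)
    )


def ramp_grid(gradient, shape=(21, 10, 21), spacing=(1.0, 2.0, 1.0)):
    """Dose increasing linearly along z at `gradient` Gy/mm."""
    origin = (-10.0, 1.0, -10.0)
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    vals = np.broadcast_to(
        100.0 + gradient * zs, shape
    ).copy()  # offset keeps doses positive
    return DoseGrid(origin=origin, spacing=spacing, values=vals)


def gaussian_grid(sigma=12.0, shape=(41, 12, 41), spacing=(1.0, 2.0, 1.0)):
    origin = (-20.0, 1.0, -20.0)
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    plane = 50.0 * np.exp(-(xx**2 + zz**2) / (2 * sigma**2))
    vals = np.repeat(plane[:, None, :], shape[1], axis=1)
    return DoseGrid(origin=origin, spacing=spacing, values=vals)


class TestDisplaceStructure:
    def test_zero_shift_identity(self):
        sc = cord_structure([3.0, 5.0])
        assert displace_structure(sc, ShiftVector()).contours == sc.contours

    def test_shift_then_inverse_recovers_vertices(self):
        sc = cord_structure([3.0, 5.0])
        s = ShiftVector(1.7, -2.3, 0.9)
        back = displace_structure(displace_structure(sc, s), -s)
        for c0, c1 in zip(sc.contours, back.contours):
            assert c1.y_slice == pytest.approx(c0.y_slice, abs=1e-12)
            np.testing.assert_allclose(c1.points, c0.points, atol=1e-12)

    def test_posterior_shift_moves_vertices_posteriorly(self):
        sc = cord_structure([3.0])
        moved = displace_structure(sc, ShiftVector(0, 0, -8.0))
        p0 = np.asarray(sc.contours[0].points)
        p1 = np.asarray(moved.contours[0].points)
        np.testing.assert_allclose(p1[:, 1], p0[:, 1] - 8.0)
        np.testing.assert_allclose(p1[:, 0], p0[:, 0])


class TestDmaxDisplaced:
    def test_zero_shift_reproduces_planned_exactly(self):
        rng = np.random.default_rng(1)
        grid = gaussian_grid()
        sc = cord_structure([3.0, 5.0, 7.0])
        est = dmax_displaced(grid, sc, ShiftVector())
        assert est.dmax_displaced == est.dmax_planned
        assert est.percent_change == 0.0

    def test_linear_ramp_shift_adds_gradient_times_distance(self):
        g = 0.8  # Gy/mm along z
        grid = ramp_grid(g)
        sc = cord_structure([3.0, 5.0], r=3.0)
        for dz in (0.4, 1.3, -2.0):
            est = dmax_displaced(grid, sc, ShiftVector(0, 0, dz))
            assert est.dmax_displaced - est.dmax_planned == pytest.approx(
                g * dz, rel=1e-6
            )

    def test_continuity_as_shift_vanishes(self):
        grid = gaussian_grid()
        sc = cord_structure([3.0, 5.0], r=3.0, cz=6.0)
        planned = dmax_displaced(grid, sc, ShiftVector()).dmax_planned
        prev_gap = None
        for mag in (4.0, 2.0, 1.0, 0.5, 0.25, 0.05):
            est = dmax_displaced(grid, sc, ShiftVector(mag, 0, mag))
            gap = abs(est.dmax_displaced - planned)
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-9
            prev_gap = gap
        assert prev_gap < 0.2

    def test_direction_invariance_on_radial_field(self):
        grid = gaussian_grid()
        sc = cord_structure([3.0, 5.0, 7.0], r=3.0)
        mags = []
        for angle in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            s = ShiftVector(3.0 * np.cos(angle), 0.0, 3.0 * np.sin(angle))
            mags.append(dmax_displaced(grid, sc, s).dmax_displaced)
        assert np.ptp(mags) < 0.05

    def test_translation_equivalence_with_shifted_grid(self):
        grid = gaussian_grid(sigma=25.0)
        sc = cord_structure([3.0, 5.0, 7.0], r=5.0, cz=2.0)
        s = ShiftVector(1.3, 0.0, -0.7)
        est = dmax_displaced(grid, sc, s)
        shifted = DoseGrid(
            origin=(
                grid.origin[0] - s.dx,
                grid.origin[1] - s.dy,
                grid.origin[2] - s.dz,
            ),
            spacing=grid.spacing,
            values=grid.values,
        )
        ref = dmax_displaced(shifted, sc, ShiftVector())
        assert est.dmax_displaced == pytest.approx(ref.dmax_planned, abs=0.1)

    def test_out_of_extent_raises_named_error(self):
        grid = gaussian_grid()
        sc = cord_structure([3.0, 5.0])
        with pytest.raises(OutOfExtentError, match="sc"):
            dmax_displaced(grid, sc, ShiftVector(500.0, 0, 0))


class TestFitDisplacedVsSetup:
    def test_collinear_pairs_give_r2_one(self):
        x = np.linspace(30, 40, 8)
        fit = fit_displaced_vs_setup(list(zip(x, 0.7 * x + 3)))
        assert fit.r_squared == pytest.approx(1.0)

    def test_identity_line(self):
        x = np.linspace(30, 40, 8)
        fit = fit_displaced_vs_setup(list(zip(x, x)))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_shift_only_course_agreement(self, shift_only_course):
        """On a shift-only synthetic cohort the estimator tracks the engine
        recomputation closely (pooled across regions)."""
        pairs = displaced_setup_pairs(shift_only_course.records)
        diffs = pairs[:, 1] - pairs[:, 0]
        assert np.abs(diffs).mean() < 0.5
        assert fit_displaced_vs_setup(pairs).r_squared > 0.95


def _estimate(region, value, constraint=40.0):
    return DisplacedEstimate(
        region=region,
        shift=ShiftVector(),
        dmax_displaced=value,
        dmax_planned=37.0,
        percent_change=0.0,
        flag=value > constraint,
        constraint=constraint,
    )


class TestTriggerReplan:
    def test_all_below_constraint_no_flag(self):
        report = trigger_replan([_estimate("C1_C3", 37.0), _estimate("C6_C7", 33.0)])
        assert not report.any_flag
        assert report.worst_region == "C1_C3"

    def test_region_just_above_constraint_is_flagged(self):
        report = trigger_replan(
            [_estimate("C1_C3", 40.1), _estimate("C4_C5", 39.9)], constraint=40.0
        )
        assert report.flagged_regions == ("C1_C3",)
        assert report.worst_dmax == pytest.approx(40.1)

    def test_prv_constraint_flags_only_above_45(self):
        ests = [_estimate("C1_C3", 44.0), _estimate("C4_C5", 45.2)]
        report = trigger_replan(ests, constraint=45.0)
        assert report.flagged_regions == ("C4_C5",)
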