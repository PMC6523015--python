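import bisect

import numpy as np
import pytest

from arcqa.correlation import (
    SHIFT_VALUES_MM,
    CorrelationCurve,
    ShiftGrid,
    build_curve_set,
    build_shift_grid,
    interpolate_curve,
    invert_curve,
    min_direction_error,
)
from arcqa.dose_model import ConeKernel
from arcqa.geometry import DIRECTIONS, PLACEMENT_LABELS, build_arccheck_geometry
from arcqa.plan_model import Beam, QAPlan, generate_body_path_plan

from _oracles import brute_force_invert


def _curve(values, direction="SI", placement="nominal"):
    return CorrelationCurve(
        diode=0, direction=direction, placement=placement,
        values_percent=tuple(values),
    )


def _linear_curve(slope):
    return _curve([slope * x for x in SHIFT_VALUES_MM])


class TestShiftGrid:
    def test_seventeen_values_per_direction(self):
        grid = build_shift_grid()
        assert grid.n_per_direction == 17
        assert len(grid.directions) == 3

    def test_quarter_mm_resolution_inside_one_mm(self):
        values = np.asarray(build_shift_grid().values_mm)
        inner = values[np.abs(values) <= 1.0]
        assert np.allclose(np.diff(inner), 0.25)
        outer = values[np.abs(values) >= 1.0]
        assert np.allclose(np.abs(np.diff(outer[outer <= -1])), 1.0)

    def test_symmetric_about_zero_and_contains_zero(self):
        values = np.asarray(build_shift_grid().values_mm)
        assert 0.0 in values
        assert np.allclose(np.sort(-values), values)

    def test_three_directions_imply_49_dose_calculations(self):
        assert build_shift_grid().n_distinct_calculations == 49


class TestBuildCurves:
    def test_21_curves_per_diode_with_zero_at_zero(self, study):
        for diode in study.curves.diodes:
            per = study.curves.curves[diode]
            assert len(per) == 21
            assert {k[0] for k in per} == set(DIRECTIONS)
            assert {k[1] for k in per} == set(PLACEMENT_LABELS)
            for curve in per.values():
                assert curve.values_percent[8] == 0.0

    def test_mu_scale_invariance(self, array, kernel):
        plan = generate_body_path_plan(n_beams=8, seed=2)
        doubled = QAPlan(
            beams=tuple(
                Beam(b.beam_id, b.source, b.direction, b.cone_diameter_mm, 2 * b.mu)
                for b in plan
            )
        )
        # pick an irradiated diode
        from arcqa.selection import build_beam_diode_lut, per_beam_signals

        lut = build_beam_diode_lut(per_beam_signals(plan, array, kernel))
        diode = lut.diodes[0]
        c1 = build_curve_set(plan, array, kernel, [diode])
        c2 = build_curve_set(doubled, array, kernel, [diode])
        for key in c1.curves[diode]:
            assert np.allclose(
                c1.curves[diode][key].array, c2.curves[diode][key].array, atol=1e-12
            )

    def test_entrance_diode_on_axis_flat_along_beam_steep_across(self, array, kernel):
        """A single anterior beam aimed through a diode: the along-beam (AP)
        curve is nearly flat at small shifts while the cross-beam curves
        fall steeply (field-centre vs field-edge geometry)."""
        diode = int(np.argmax(array.positions[:, 1]))  # most anterior diode
        target = array.positions[diode]
        src = target + np.array([0.0, 800.0, 0.0])
        iso = target - np.array([0.0, 105.0, 0.0])
        d = (iso - src) / np.linalg.norm(iso - src)
        sad = np.linalg.norm(iso - src)
        plan = QAPlan(
            beams=(Beam(0, tuple(src), tuple(d)),), isocenter=tuple(iso)
        )
        curves = build_curve_set(plan, array, kernel, [diode])
        ap = curves.curve(diode, "AP").array
        lr = curves.curve(diode, "LR").array
        si = curves.curve(diode, "SI").array
        i1 = SHIFT_VALUES_MM.index(1.0)
        assert abs(ap[i1]) < 1.0  # sub-percent along the axis
        assert abs(lr[i1]) > 5 * abs(ap[i1])
        assert abs(si[i1]) > 5 * abs(ap[i1])

    def test_zero_dose_diode_skipped_with_warning(self, array, kernel, caplog):
        plan = generate_body_path_plan(n_beams=2, seed=1)
        # find a diode with no dose at all
        from arcqa.dose_model import compute_delivery_dose

        doses = compute_delivery_dose(plan, array, kernel).values
        dark = int(np.argmin(doses))
        assert doses[dark] == 0.0
        import logging

        with caplog.at_level(logging.WARNING):
            curves = build_curve_set(plan, array, kernel, [dark])
        assert dark not in curves.curves


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        curve = _linear_curve(3.0)
        for x, y in zip(SHIFT_VALUES_MM, curve.values_percent):
            assert interpolate_curve(curve, x) == pytest.approx(y, abs=1e-12)

    def test_midpoint_of_linear_segment(self):
        curve = _linear_curve(4.0)
        assert interpolate_curve(curve, 0.125) == pytest.approx(0.5)

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError):
            interpolate_curve(_linear_curve(1.0), 5.001)

    def test_matches_independent_two_point_oracle(self, study):
        """1000 random shifts against a bisect-based two-point formula."""
        rng = np.random.default_rng(8)
        xs = np.asarray(SHIFT_VALUES_MM)
        diodes = study.curves.diodes
        for _ in range(1000):
            diode = diodes[rng.integers(len(diodes))]
            direction = DIRECTIONS[rng.integers(3)]
            curve = study.curves.curve(diode, direction)
            delta = rng.uniform(-5, 5)
            i = bisect.bisect_right(xs, delta) - 1
            i = min(max(i, 0), len(xs) - 2)
            y0, y1 = curve.values_percent[i], curve.values_percent[i + 1]
            t = (delta - xs[i]) / (xs[i + 1] - xs[i])
            expected = y0 + t * (y1 - y0)
            assert interpolate_curve(curve, delta) == pytest.approx(expected, abs=1e-12)


class TestInversion:
    def test_zero_rpd_returns_zero(self):
        delta, solvable = invert_curve(_linear_curve(2.0), 0.0)
        assert delta == 0.0 and solvable

    def test_linear_curve_closed_form(self):
        for slope, rpd in [(2.0, 3.0), (-4.0, 2.0), (10.0, -25.0)]:
            delta, solvable = invert_curve(_linear_curve(slope), rpd)
            assert solvable
            assert delta == pytest.approx(rpd / slope, abs=1e-12)

    def test_no_root_flagged_with_nearest_value(self):
        delta, solvable = invert_curve(_linear_curve(1.0), 99.0)
        assert not solvable
        assert delta == 5.0  # the node closest in value to an unreachable level

    def test_matches_brute_force_scan_on_sampled_curves(self, study):
        rng = np.random.default_rng(15)
        diodes = study.curves.diodes
        for _ in range(200):
            diode = diodes[rng.integers(len(diodes))]
            direction = DIRECTIONS[rng.integers(3)]
            placement = PLACEMENT_LABELS[rng.integers(7)]
            curve = study.curves.curve(diode, direction, placement)
            span = np.abs(curve.array).max()
            rpd = rng.uniform(-1.2 * span, 1.2 * span)
            delta, solvable = invert_curve(curve, rpd)
            ref, ref_solvable = brute_force_invert(curve, rpd)
            assert solvable == ref_solvable
            assert delta == pytest.approx(ref, abs=0.002)

    def test_right_inverse_property(self, study):
        """Inverting a curve's own value at any node recovers a shift with
        the same curve value and no larger magnitude."""
        for diode in study.curves.diodes[:10]:
            curve = study.curves.curve(diode, "SI")
            for x, y in zip(SHIFT_VALUES_MM, curve.values_percent):
                delta, solvable = invert_curve(curve, y)
                assert solvable
                assert abs(interpolate_curve(curve, delta) - y) < 1e-9
                assert abs(delta) <= abs(x) + 1e-12


class TestMinDirectionError:
    def _three(self, ap, si, lr):
        return {
            "AP": _curve(ap, "AP"),
            "SI": _curve(si, "SI"),
            "LR": _curve(lr, "LR"),
        }

    def test_zero_rpd_gives_zero_everywhere(self):
        curves = self._three(*[[2 * x for x in SHIFT_VALUES_MM]] * 3)
        abs_d, _, delta, solvable = min_direction_error(curves, 0.0)
        assert abs_d == 0.0 and delta == 0.0 and solvable

    def test_flat_direction_discarded_in_favour_of_steep(self):
        flat = [0.009 * np.sign(x) for x in SHIFT_VALUES_MM]  # |C| < 0.01%
        steep = [10.0 * x for x in SHIFT_VALUES_MM]
        curves = self._three(ap=flat, si=steep, lr=steep)
        abs_d, direction, delta, solvable = min_direction_error(curves, 1.0)
        assert direction in ("SI", "LR")
        assert abs_d == pytest.approx(0.1)
        assert solvable

    def test_order_invariance(self):
        a = [1.0 * x for x in SHIFT_VALUES_MM]
        b = [5.0 * x for x in SHIFT_VALUES_MM]
        c = [0.5 * x for x in SHIFT_VALUES_MM]
        res1 = min_direction_error(self._three(a, b, c), 2.0)
        shuffled = dict(reversed(list(self._three(a, b, c).items())))
        res2 = min_direction_error(shuffled, 2.0)
        assert res1 == res2

    def test_requires_exactly_three_directions(self):
        with pytest.raises(ValueError):
            min_direction_error({"AP": _linear_curve(1.0)}, 1.0)
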