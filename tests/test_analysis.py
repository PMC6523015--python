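import numpy as np
import pytest

from arcqa.analysis import (
    Baseline,
    PlacementLUT,
    build_placement_lut,
    compute_baseline,
    compute_rpd,
    detect_systematic_shift,
    position_errors,
    reproducibility_errors,
    same_day_relative_sd,
)
from arcqa.correlation import (
    SHIFT_VALUES_MM,
    CorrelationCurve,
    CurveSet,
    ShiftGrid,
    min_direction_error,
)
from arcqa.dose_model import DoseVector
from arcqa.geometry import DIRECTIONS, PLACEMENT_LABELS
from arcqa.selection import BeamDiodeLUT
from arcqa.simulator import NoiseModel, simulate_campaign


def _vec(values, label=""):
    return DoseVector(values=np.asarray(values, dtype=float), label=label)


def _lut(n_diodes):
    return BeamDiodeLUT(mapping={i: i for i in range(n_diodes)}, threshold=0.0)


def _synthetic_curves(slopes_by_diode):
    """Curve set with given per-(diode, direction) slopes, identical for
    all 7 placements."""
    curves = {}
    for diode, slopes in slopes_by_diode.items():
        per = {}
        for direction in DIRECTIONS:
            values = tuple(slopes[direction] * x for x in SHIFT_VALUES_MM)
            for placement in PLACEMENT_LABELS:
                per[(direction, placement)] = CorrelationCurve(
                    diode=diode, direction=direction, placement=placement,
                    values_percent=values,
                )
        curves[diode] = per
    return CurveSet(grid=ShiftGrid(), curves=curves)


class TestBaseline:
    def test_mean_of_identical_deliveries_is_any_one(self):
        d = _vec([1.0, 2.0, 3.0])
        base = compute_baseline([d, d, d])
        assert np.array_equal(base.values, d.values)

    def test_simple_arithmetic_mean(self):
        base = compute_baseline([_vec([98.0]), _vec([102.0])])
        assert base.values[0] == pytest.approx(100.0)

    def test_order_invariance(self):
        a, b, c = _vec([1, 5, 2]), _vec([3, 1, 9]), _vec([2, 0, 4])
        assert np.array_equal(
            compute_baseline([a, b, c]).values, compute_baseline([c, a, b]).values
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline([_vec([1.0]), _vec([1.0, 2.0])])

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            compute_baseline([_vec([1.0])])


class TestRPD:
    def test_measurement_equal_to_baseline_gives_zero(self):
        base = compute_baseline([_vec([10.0, 20.0])] * 2)
        rpd = compute_rpd(_vec([10.0, 20.0]), base, _lut(2))
        assert rpd.values == {0: 0.0, 1: 0.0}

    def test_two_percent_increase(self):
        base = compute_baseline([_vec([50.0, 80.0])] * 2)
        rpd = compute_rpd(_vec([51.0, 81.6]), base, _lut(2))
        assert rpd.values[0] == pytest.approx(2.0)
        assert rpd.values[1] == pytest.approx(2.0)

    def test_linearity_in_the_measurement(self):
        base = compute_baseline([_vec([40.0])] * 2)
        lut = _lut(1)
        r1 = compute_rpd(_vec([44.0]), base, lut).values[0]
        r2 = compute_rpd(_vec([42.0]), base, lut).values[0]
        assert r1 - r2 == pytest.approx(100.0 * 2.0 / 40.0)

    def test_nonpositive_baseline_diode_dropped(self, caplog):
        import logging

        base = Baseline(values=np.array([10.0, 0.0]), n_deliveries=2)
        with caplog.at_level(logging.WARNING):
            rpd = compute_rpd(_vec([11.0, 5.0]), base, _lut(2))
        assert 1 not in rpd.values


class TestPlacementLUT:
    def test_zero_variance_ties_to_nominal(self):
        curves = _synthetic_curves({0: {"AP": 1.0, "SI": 5.0, "LR": 0.5}})
        deliveries = [_vec([10.0])] * 5
        plut = build_placement_lut(deliveries, curves, _lut(1))
        assert plut.placements == {0: "nominal"}

    def test_one_entry_per_monitored_diode(self, study):
        campaign = simulate_campaign(
            study.plan, study.array, study.kernel, NoiseModel(), seed=3
        )
        plut = build_placement_lut(campaign.same_day, study.curves, study.lut)
        assert set(plut.placements) == set(study.lut.diodes)

    def test_chosen_placement_no_worse_than_nominal(self, study):
        """The frozen placement hypothesis never yields a larger inverted
        same-day error than the nominal hypothesis would."""
        campaign = simulate_campaign(
            study.plan, study.array, study.kernel, NoiseModel(), seed=4
        )
        rel_sd = same_day_relative_sd(campaign.same_day, study.lut)
        plut = build_placement_lut(campaign.same_day, study.curves, study.lut)
        for diode, s in rel_sd.items():
            chosen = min_direction_error(
                study.curves.direction_curves(diode, plut.get(diode)), s
            )[0]
            nominal = min_direction_error(
                study.curves.direction_curves(diode, "nominal"), s
            )[0]
            assert chosen <= nominal + 1e-12


class TestReproducibility:
    def test_zero_variance_gives_zero_errors(self):
        curves = _synthetic_curves({0: {"AP": 1.0, "SI": 5.0, "LR": 0.5}})
        deliveries = [_vec([10.0])] * 5
        plut = PlacementLUT(placements={0: "nominal"})
        rep = reproducibility_errors(deliveries, curves, plut, _lut(1), k=1)
        assert rep.rms_mm == 0.0
        assert rep.summary["max_abs_mm"] == 0.0

    def test_two_sd_errors_dominate_one_sd_on_monotone_curves(self):
        """On strictly monotone curves, doubling the inverted SD level
        cannot shrink any per-diode error."""
        curves = _synthetic_curves(
            {0: {"AP": 2.0, "SI": 8.0, "LR": 1.0}, 1: {"AP": 3.0, "SI": 1.0, "LR": 6.0}}
        )
        rng = np.random.default_rng(5)
        deliveries = [_vec(100.0 + rng.normal(0, 1.0, size=2)) for _ in range(5)]
        plut = PlacementLUT(placements={0: "nominal", 1: "nominal"})
        lut = _lut(2)
        r1 = reproducibility_errors(deliveries, curves, plut, lut, k=1)
        r2 = reproducibility_errors(deliveries, curves, plut, lut, k=2)
        merged = r1.table.merge(r2.table, on="diode", suffixes=("_1", "_2"))
        assert (merged["abs_mm_2"] >= merged["abs_mm_1"] - 1e-12).all()

    def test_scale_invariance(self):
        curves = _synthetic_curves({0: {"AP": 2.0, "SI": 8.0, "LR": 1.0}})
        rng = np.random.default_rng(6)
        base = [100.0 + rng.normal(0, 1.0) for _ in range(5)]
        plut = PlacementLUT(placements={0: "nominal"})
        lut = _lut(1)
        r1 = reproducibility_errors([_vec([v]) for v in base], curves, plut, lut)
        r2 = reproducibility_errors([_vec([2 * v]) for v in base], curves, plut, lut)
        assert r1.table["delta_mm"][0] == pytest.approx(r2.table["delta_mm"][0], abs=1e-12)


class TestPositionErrors:
    def _setup(self, slopes={"AP": 2.0, "SI": 8.0, "LR": 1.0}):
        curves = _synthetic_curves({0: slopes})
        plut = PlacementLUT(placements={0: "nominal"})
        return curves, plut, _lut(1)

    def test_rpd_equal_to_margin_cancels_exactly(self):
        from arcqa.analysis import RPDMap

        curves, plut, lut = self._setup()
        rep = position_errors(RPDMap(values={0: 1.0}), curves, plut, lut, 1.0)
        assert rep.table["delta_mm"][0] == 0.0
        assert rep.table["branch_percent"][0] == -1.0

    def test_zero_margin_reduces_to_step_one(self):
        from arcqa.analysis import RPDMap

        curves, plut, lut = self._setup()
        rpd = 3.7
        rep = position_errors(RPDMap(values={0: rpd}), curves, plut, lut, 0.0)
        expected = min_direction_error(curves.direction_curves(0, "nominal"), rpd)
        assert rep.table["delta_mm"][0] == pytest.approx(expected[2], abs=1e-12)
        assert rep.table["direction"][0] == expected[1]

    def test_margin_never_worse_than_no_margin(self, study):
        from arcqa.analysis import RPDMap

        rng = np.random.default_rng(7)
        values = {d: float(rng.normal(0, 3.0)) for d in study.lut.diodes}
        plut = PlacementLUT(placements={})
        m0 = position_errors(RPDMap(values=values), study.curves, plut, study.lut, 0.0)
        m1 = position_errors(RPDMap(values=values), study.curves, plut, study.lut, 1.0)
        merged = m0.table.merge(m1.table, on="diode", suffixes=("_0", "_1"))
        assert (merged["abs_mm_1"] <= merged["abs_mm_0"] + 1e-12).all()

    def test_summary_statistics_consistent(self, study):
        from arcqa.analysis import RPDMap

        rng = np.random.default_rng(8)
        values = {d: float(rng.normal(0, 2.0)) for d in study.lut.diodes}
        rep = position_errors(
            RPDMap(values=values), study.curves, PlacementLUT(placements={}), study.lut
        )
        deltas = rep.table["delta_mm"].to_numpy()
        assert rep.summary["rms_mm"] == pytest.approx(
            float(np.sqrt(np.mean(deltas**2))), abs=1e-12
        )
        assert rep.summary["max_abs_mm"] >= rep.summary["rms_mm"]
        assert rep.summary["mean_abs_mm"] == pytest.approx(
            float(np.mean(np.abs(deltas))), abs=1e-12
        )


class TestDetection:
    def _report(self, mean_abs, rms):
        import pandas as pd

        from arcqa.analysis import PositionErrorReport

        return PositionErrorReport(
            table=pd.DataFrame(),
            summary={
                "mean_abs_mm": mean_abs,
                "rms_mm": rms,
                "within_tolerance": rms <= 0.5,
            },
        )

    def test_detects_when_mean_exceeds_null_quantile(self):
        verdict = detect_systematic_shift(self._report(0.2, 0.3), [0.01, 0.02, 0.03])
        assert verdict["detected"] and verdict["exceeds_null_q95"]

    def test_rms_branch_still_fires_with_unbeatable_null(self):
        verdict = detect_systematic_shift(
            self._report(0.2, 0.7), {"q95_mean_abs_mm": float("inf")}
        )
        assert verdict["detected"]
        assert not verdict["exceeds_null_q95"]
        assert verdict["exceeds_rms_tolerance"]

    def test_quiet_measurement_not_flagged(self):
        verdict = detect_systematic_shift(
            self._report(0.02, 0.04), {"q95_mean_abs_mm": 0.05}
        )
        assert not verdict["detected"]

    def test_missing_null_reference_refused(self):
        with pytest.raises(ValueError, match="simulate null"):
            detect_systematic_shift(self._report(0.1, 0.1), [])
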