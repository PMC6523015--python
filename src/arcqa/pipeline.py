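"""High-level drivers: build a study once, then run simulated campaigns.

A *study setup* is everything the estimator needs before any measurement:
the array geometry, the body-path plan, the dose kernel, the beam->diode
lookup table and the 21-per-diode correlation curves.  It is deterministic
given the plan seed.  On top of it, campaign drivers run the full
measurement->analysis chain for null (constancy) and introduced-shift
studies, which is what both the command line and the acceptance checks
use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .analysis import (
    PlacementLUT,
    PositionErrorReport,
    build_placement_lut,
    compute_baseline,
    compute_rpd,
    position_errors,
)
from .correlation import CurveSet, build_curve_set
from .dose_model import ConeKernel
from .geometry import DiodeArray, build_arccheck_geometry
from .plan_model import QAPlan, Workspace, generate_body_path_plan
from .selection import BeamDiodeLUT, build_beam_diode_lut, exclude_opposing, per_beam_signals
from .simulator import Campaign, NoiseModel, simulate_campaign

__all__ = [
    "StudySetup",
    "build_study",
    "analyze_campaign",
    "run_constancy_seeds",
    "null_reference",
]


@dataclass
class StudySetup:
    """Deterministic per-installation state of the constancy test."""

    array: DiodeArray
    plan: QAPlan
    kernel: ConeKernel
    lut: BeamDiodeLUT
    curves: CurveSet

    @property
    def n_selected(self) -> int:
        return len(self.lut)


def build_study(
    plan_seed: int = 0,
    n_beams: int = 116,
    workspace: Workspace | None = None,
    kernel: ConeKernel | None = None,
    threshold_fraction: float = 0.10,
    threshold_reference: str = "global",
    opposing_tol_deg: float = 5.0,
    array: DiodeArray | None = None,
) -> StudySetup:
    """Build geometry, plan, selection LUT and correlation curves."""
    array = array or build_arccheck_geometry()
    kernel = kernel or ConeKernel()
    plan = generate_body_path_plan(n_beams=n_beams, seed=plan_seed, workspace=workspace)
    signals = per_beam_signals(plan, array, kernel)
    lut = build_beam_diode_lut(signals, threshold_fraction, threshold_reference)
    lut = exclude_opposing(lut, plan, signals, opposing_tol_deg)
    curves = build_curve_set(plan, array, kernel, lut.diodes)
    return StudySetup(array=array, plan=plan, kernel=kernel, lut=lut, curves=curves)


def analyze_campaign(
    setup: StudySetup,
    campaign: Campaign,
    margin_percent: float = 1.0,
) -> tuple[PlacementLUT, dict[str, PositionErrorReport]]:
    """Full three-step analysis of one simulated campaign."""
    baseline = compute_baseline(campaign.baseline)
    placement_lut = build_placement_lut(campaign.same_day, setup.curves, setup.lut)
    reports: dict[str, PositionErrorReport] = {}
    for name, measurement in campaign.tests.items():
        rpd = compute_rpd(measurement, baseline, setup.lut)
        reports[name] = position_errors(
            rpd, setup.curves, placement_lut, setup.lut, margin_percent
        )
    return placement_lut, reports


def run_constancy_seeds(
    setup: StudySetup,
    seeds: Sequence[int],
    test_shifts: Mapping[str, Sequence[float]] | None = None,
    noise: NoiseModel | None = None,
    margin_percent: float = 1.0,
) -> dict[str, list[dict]]:
    """Run one campaign per seed; collect per-test summary statistics.

    Returns a mapping test label -> list of summary dicts (one per seed,
    each with the seed attached).
    """
    noise = noise if noise is not None else NoiseModel()
    shifts = dict(test_shifts or {"constancy": (0.0, 0.0, 0.0)})
    out: dict[str, list[dict]] = {name: [] for name in shifts}
    for seed in seeds:
        campaign = simulate_campaign(
            setup.plan, setup.array, setup.kernel, noise, int(seed), test_shifts=shifts
        )
        _, reports = analyze_campaign(setup, campaign, margin_percent)
        for name, report in reports.items():
            out[name].append({"seed": int(seed), **report.summary})
    return out


def null_reference(summaries: Sequence[Mapping]) -> dict:
    """Null-distribution reference for drift detection, from zero-shift runs."""
    means = np.array([s["mean_abs_mm"] for s in summaries], dtype=float)
    if len(means) < 2:
        raise ValueError("need at least two null summaries")
    return {
        "n_seeds": int(len(means)),
        "q95_mean_abs_mm": float(np.quantile(means, 0.95)),
        "mean_abs_mm_values": [float(v) for v in means],
    }
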