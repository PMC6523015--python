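"""Synthetic delivery generator emulating the physical measurement campaign.

A measurement campaign for the constancy test consists of a six-delivery
baseline (different days), a five-delivery same-day reproducibility set,
and test deliveries with optional introduced alignment shifts.  The noise
model mirrors the stated instrument budget:

* day-to-day machine output constancy: 1% SD (one factor per day);
* same-day output constancy: 0.5% SD (one factor per delivery);
* per-diode dose consistency: 0.5% SD per delivery (the 1% consistency
  plus 0.5% linearity budget, split between the static part that cancels
  against the baseline and the per-delivery part modelled here);
* diode placement: one static truncated-Gaussian offset per diode,
  0.25 mm SD per axis, never exceeding the stated 0.5 mm accuracy.

All factors are multiplicative lognormal (the SDs are small, so effectively
Gaussian).  An introduced alignment shift — physically, pulling the
phantom insert out along SI — is a rigid translation of the whole phantom.
Every random draw descends from one master seed through named substreams,
and the truth behind each delivery is recorded in a manifest for recovery
scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import build_curve_set, interpolate_curve
from .dose_model import ConeKernel, DoseVector, compute_delivery_dose
from .geometry import DIRECTION_VECTORS, DIRECTIONS, DiodeArray
from .plan_model import QAPlan
from .selection import BeamDiodeLUT

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseModel",
    "TruthState",
    "Campaign",
    "simulate_delivery",
    "simulate_campaign",
    "verify_curves",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise budget of machine and detector."""

    day_output_sd: float = 0.01
    same_day_output_sd: float = 0.005
    diode_consistency_sd: float = 0.005
    linearity_bound: float = 0.005  # folded into the consistency SD
    placement_sd_mm: float = 0.25
    placement_max_mm: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "day_output_sd",
            "same_day_output_sd",
            "diode_consistency_sd",
            "linearity_bound",
            "placement_sd_mm",
            "placement_max_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """Noise-free model (for exact end-to-end null checks)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TruthState:
    """Ground truth behind a simulated delivery, recorded for scoring."""

    global_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    per_beam_offsets: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    placement_offsets: np.ndarray | None = None  # (n_diodes, 3) mm

    def to_manifest(self) -> dict:
        entry = {
            "global_shift_mm": [float(c) for c in self.global_shift],
            "per_beam_offsets_mm": {
                str(b): [float(c) for c in v] for b, v in self.per_beam_offsets.items()
            },
        }
        if self.placement_offsets is not None:
            entry["placement_offsets_mm"] = [
                [round(float(c), 6) for c in row] for row in self.placement_offsets
            ]
        return entry

    @classmethod
    def from_manifest(cls, entry: Mapping) -> "TruthState":
        placements = entry.get("placement_offsets_mm")
        return cls(
            global_shift=tuple(float(c) for c in entry["global_shift_mm"]),
            per_beam_offsets={
                int(b): tuple(float(c) for c in v)
                for b, v in entry.get("per_beam_offsets_mm", {}).items()
            },
            placement_offsets=None if placements is None else np.asarray(placements, float),
        )


def _lognormal_factor(rng: np.random.Generator, sd: float, size=None):
    if sd == 0.0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


def _truncated_normal(
    rng: np.random.Generator, sd: float, bound: float, size: tuple[int, ...]
) -> np.ndarray:
    """Gaussian draws resampled until within +-bound (exact truncation)."""
    if sd == 0.0 or bound == 0.0:
        return np.zeros(size)
    x = rng.normal(0.0, sd, size=size)
    for _ in range(100):
        bad = np.abs(x) > bound
        if not bad.any():
            break
        x[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
    return np.clip(x, -bound, bound)


def draw_placement_truth(
    rng: np.random.Generator, n_diodes: int, noise: NoiseModel
) -> np.ndarray:
    """Static true placement offsets of all diodes, (n, 3) mm."""
    return _truncated_normal(
        rng, noise.placement_sd_mm, noise.placement_max_mm, (n_diodes, 3)
    )


def simulate_delivery(
    plan: QAPlan,
    array: DiodeArray,
    kernel: ConeKernel,
    truth: TruthState,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    day_factor: float | None = None,
    label: str = "",
) -> DoseVector:
    """One noisy delivery: deterministic given the seed.

    ``day_factor`` lets a campaign share one day-level output factor among
    same-day deliveries; when omitted, a fresh one is drawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = compute_delivery_dose(
        plan,
        array,
        kernel,
        placements=truth.placement_offsets,
        global_shift=truth.global_shift,
        per_beam_source_offsets=truth.per_beam_offsets or None,
        label=label,
    )
    if day_factor is None:
        day_factor = float(_lognormal_factor(rng, noise.day_output_sd))
    output = day_factor * float(_lognormal_factor(rng, noise.same_day_output_sd))
    per_diode = _lognormal_factor(rng, noise.diode_consistency_sd, size=len(clean))
    return DoseVector(values=clean.values * output * per_diode, label=label)


@dataclass
class Campaign:
    """Labelled delivery set of one simulated measurement campaign."""

    baseline: list[DoseVector]
    same_day: list[DoseVector]
    tests: dict[str, DoseVector]
    placement_truth: np.ndarray
    manifest: dict


def simulate_campaign(
    plan: QAPlan,
    array: DiodeArray,
    kernel: ConeKernel,
    noise: NoiseModel,
    seed: int,
    test_shifts: Mapping[str, Sequence[float]] | None = None,
    n_baseline: int = 6,
    n_same_day: int = 5,
) -> Campaign:
    """Simulate baseline, same-day and test deliveries under one truth.

    ``test_shifts`` maps a label to an introduced alignment-shift vector
    (mm); by default a single zero-shift constancy measurement is made.
    The baseline deliveries fall on distinct days; the same-day set shares
    one day-level output factor; each test delivery gets its own day.
    """
    if n_baseline < 2 or n_same_day < 3:
        raise ValueError("need >=2 baseline and >=3 same-day deliveries")
    test_shifts = dict(test_shifts or {"constancy": (0.0, 0.0, 0.0)})
    master = np.random.SeedSequence(seed)
    streams = master.spawn(3)
    rng_truth = np.random.default_rng(streams[0])
    rng_base = np.random.default_rng(streams[1])
    rng_rest = np.random.default_rng(streams[2])

    placement_truth = draw_placement_truth(rng_truth, array.count, noise)
    static_truth = TruthState(placement_offsets=placement_truth)

    manifest: dict = {
        "seed": seed,
        "noise": asdict(noise),
        "deliveries": [],
    }

    baseline = []
    for i in range(n_baseline):
        label = f"baseline-{i}"
        v = simulate_delivery(
            plan, array, kernel, static_truth, noise, rng_base, label=label
        )
        baseline.append(v)
        manifest["deliveries"].append(
            {"label": label, "day_group": f"day-b{i}", "truth": {"global_shift_mm": [0.0, 0.0, 0.0], "per_beam_offsets_mm": {}}}
        )

    same_day = []
    day_factor = float(_lognormal_factor(rng_rest, noise.day_output_sd))
    for i in range(n_same_day):
        label = f"same-day-{i}"
        v = simulate_delivery(
            plan, array, kernel, static_truth, noise, rng_rest,
            day_factor=day_factor, label=label,
        )
        same_day.append(v)
        manifest["deliveries"].append(
            {"label": label, "day_group": "day-s", "truth": {"global_shift_mm": [0.0, 0.0, 0.0], "per_beam_offsets_mm": {}}}
        )

    tests: dict[str, DoseVector] = {}
    for name, shift in test_shifts.items():
        truth = TruthState(
            global_shift=tuple(float(c) for c in shift),
            placement_offsets=placement_truth,
        )
        v = simulate_delivery(
            plan, array, kernel, truth, noise, rng_rest, label=name
        )
        tests[name] = v
        manifest["deliveries"].append(
            {"label": name, "day_group": f"day-{name}", "truth": truth.to_manifest() | {"placement_offsets_mm": None}}
        )
    # record the static placement truth once
    manifest["placement_offsets_mm"] = [
        [round(float(c), 6) for c in row] for row in placement_truth
    ]
    return Campaign(
        baseline=baseline,
        same_day=same_day,
        tests=tests,
        placement_truth=placement_truth,
        manifest=manifest,
    )


def verify_curves(
    plan: QAPlan,
    array: DiodeArray,
    kernel: ConeKernel,
    lut: BeamDiodeLUT,
    beam_ids: Sequence[int],
    shifts_mm: Sequence[float] = (-1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0),
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Curve-consistency check at selected beams.

    Emulates stopping the delivery at a node and shifting that beam alone
    (a robot-mastering pointing offset): per direction and shift, the
    simulated single-beam percent dose change at the matched diode is
    tabulated against the single-beam correlation-curve prediction.  A
    beam shift of +s is geometrically equivalent to a phantom shift of -s.
    """
    noise = noise or NoiseModel.zero()
    rng = np.random.default_rng(seed)
    if any(abs(s) > 2.0 for s in shifts_mm):
        raise ValueError("verification shifts must stay within +-2 mm")
    rows = []
    for beam_id in beam_ids:
        if beam_id not in lut.mapping:
            raise KeyError(f"beam {beam_id} has no matched diode in the LUT")
        diode = lut.mapping[beam_id]
        single = QAPlan(
            beams=(plan.beam(beam_id),),
            label=f"{plan.label}:beam-{beam_id}",
            isocenter=plan.isocenter,
        )
        curves = build_curve_set(single, array, kernel, [diode])
        ref = simulate_delivery(
            single, array, kernel, TruthState(), NoiseModel.zero(), rng
        ).values[diode]
        for direction in DIRECTIONS:
            curve = curves.curve(diode, direction)
            e = DIRECTION_VECTORS[direction]
            for s in shifts_mm:
                truth = TruthState(per_beam_offsets={beam_id: tuple(s * e)})
                measured = simulate_delivery(
                    single, array, kernel, truth, noise, rng
                ).values[diode]
                measured_pct = 100.0 * (measured - ref) / ref
                predicted_pct = interpolate_curve(curve, -s)
                rows.append(
                    {
                        "beam": beam_id,
                        "diode": diode,
                        "direction": direction,
                        "beam_shift_mm": s,
                        "measured_percent": measured_pct,
                        "predicted_percent": predicted_pct,
                        "diff_percent": measured_pct - predicted_pct,
                    }
                )
    return pd.DataFrame(rows)
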