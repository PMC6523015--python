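"""Correlation curves of dose change versus position shift, and their inversion.

For every selected diode, 21 correlation curves are built: 3 clinical
directions (AP, SI, LR) x 7 placement hypotheses (nominal and +-0.5 mm per
axis).  A curve samples

    C(delta) = 100 * (D(delta) - D(0)) / D(0)   [percent]

on a 17-point shift grid spanning -5..5 mm with 0.25 mm resolution inside
+-1 mm and 1 mm resolution outside.  Because the three directions share the
single unshifted calculation, a full curve set costs 3 x 16 + 1 = 49
distinct dose calculations.

Inversion maps a measured relative percent difference back to a shift:
roots of the piecewise-linear interpolant are found exactly; of several
roots the one of smallest magnitude is returned (the method deliberately
under- rather than over-estimates), ties resolved toward the negative
root.  When no root exists the grid shift minimising |C - rpd| is returned
and flagged unsolvable.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    DIRECTION_VECTORS,
    DIRECTIONS,
    PLACEMENT_LABELS,
    DiodeArray,
    placement_vector,
)
from .dose_model import ConeKernel, PhantomCylinder, delivery_dose_at_points
from .plan_model import QAPlan

logger = logging.getLogger(__name__)

__all__ = [
    "SHIFT_VALUES_MM",
    "ShiftGrid",
    "CorrelationCurve",
    "CurveSet",
    "build_shift_grid",
    "build_curve_set",
    "interpolate_curve",
    "invert_curve",
    "min_direction_error",
]

#: The shift-grid sample points in mm: 0.25 mm spacing inside [-1, 1],
#: 1 mm spacing outside, out to +-5 mm.
SHIFT_VALUES_MM: tuple[float, ...] = (
    -5.0, -4.0, -3.0, -2.0, -1.0, -0.75, -0.5, -0.25,
    0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0,
)


@dataclass(frozen=True)
class ShiftGrid:
    """Per-direction ordered shift values shared by all curves."""

    values_mm: tuple[float, ...] = SHIFT_VALUES_MM
    directions: tuple[str, ...] = DIRECTIONS

    def __post_init__(self) -> None:
        v = np.asarray(self.values_mm)
        if not np.all(np.diff(v) > 0):
            raise ValueError("shift values must be strictly increasing")
        if 0.0 not in self.values_mm:
            raise ValueError("shift grid must contain zero")
        if not np.allclose(np.sort(-v), v):
            raise ValueError("shift grid must be symmetric about zero")

    @property
    def n_per_direction(self) -> int:
        return len(self.values_mm)

    @property
    def n_distinct_calculations(self) -> int:
        """Distinct dose calculations implied: the three directions share
        the single zero-shift calculation."""
        nonzero = sum(1 for v in self.values_mm if v != 0.0)
        return len(self.directions) * nonzero + 1

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values_mm, dtype=float)


def build_shift_grid() -> ShiftGrid:
    """The canonical 17-point shift grid for each of the three directions."""
    return ShiftGrid()


@dataclass(frozen=True)
class CorrelationCurve:
    """Sampled dose-variation-vs-shift curve for one diode, direction and
    placement hypothesis."""

    diode: int
    direction: str
    placement: str
    values_percent: tuple[float, ...]
    grid: ShiftGrid = field(default_factory=ShiftGrid)

    def __post_init__(self) -> None:
        if self.direction not in self.grid.directions:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.placement not in PLACEMENT_LABELS:
            raise ValueError(f"unknown placement {self.placement!r}")
        v = np.asarray(self.values_percent, dtype=float)
        if len(v) != self.grid.n_per_direction:
            raise ValueError("curve must have one value per grid shift")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        zero_idx = self.grid.values_mm.index(0.0)
        if v[zero_idx] != 0.0:
            raise ValueError("C(0) must be exactly zero")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values_percent, dtype=float)


@dataclass
class CurveSet:
    """21 correlation curves per selected diode (3 directions x 7 placements)."""

    grid: ShiftGrid
    curves: dict[int, dict[tuple[str, str], CorrelationCurve]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for diode, d in self.curves.items():
            if len(d) != len(DIRECTIONS) * len(PLACEMENT_LABELS):
                raise ValueError(
                    f"diode {diode} must carry exactly "
                    f"{len(DIRECTIONS) * len(PLACEMENT_LABELS)} curves, got {len(d)}"
                )

    @property
    def diodes(self) -> list[int]:
        return sorted(self.curves)

    def curve(self, diode: int, direction: str, placement: str = "nominal") -> CorrelationCurve:
        return self.curves[diode][(direction, placement)]

    def direction_curves(self, diode: int, placement: str) -> dict[str, CorrelationCurve]:
        """The three direction curves of one diode at one placement."""
        return {d: self.curves[diode][(d, placement)] for d in DIRECTIONS}


def build_curve_set(
    plan: QAPlan,
    array: DiodeArray,
    kernel: ConeKernel,
    diode_subset: Sequence[int],
    grid: ShiftGrid | None = None,
    dose_fn=None,
) -> CurveSet:
    """Build the 21 curves of every diode in ``diode_subset``.

    Each sampled value is the full-plan dose at the diode's hypothesised
    position under a rigid phantom shift ``delta`` along one clinical
    direction, normalised to the unshifted dose of the same hypothesis.
    Diodes with zero unshifted nominal dose are skipped with a warning.

    ``dose_fn(points, shift) -> doses`` overrides the forward model, e.g.
    to sample pre-computed per-shift dose grids instead of the kernel.
    """
    diode_subset = sorted(set(int(i) for i in diode_subset))
    if not diode_subset:
        raise ValueError("diode subset must be non-empty")
    grid = grid or ShiftGrid()
    n = len(diode_subset)
    placement_vecs = np.stack([placement_vector(lab) for lab in PLACEMENT_LABELS])
    # hypothesised positions: (n, 7, 3)
    base = array.positions[diode_subset][:, None, :] + placement_vecs[None, :, :]
    flat = base.reshape(-1, 3)

    def plan_dose(shift: np.ndarray) -> np.ndarray:
        if dose_fn is not None:
            return np.asarray(dose_fn(flat, shift), dtype=float).reshape(
                n, len(PLACEMENT_LABELS)
            )
        cyl = PhantomCylinder(radius_mm=array.radius_mm, center=tuple(shift))
        return delivery_dose_at_points(plan, flat + shift, kernel, cyl).reshape(n, len(PLACEMENT_LABELS))

    d0 = plan_dose(np.zeros(3))  # shared zero-shift calculation
    keep = d0[:, 0] > 0.0
    for i, ok in zip(diode_subset, keep):
        if not ok:
            logger.warning("diode %d has zero unshifted dose; skipped", i)
    zero_idx = grid.values_mm.index(0.0)

    samples: dict[str, np.ndarray] = {}
    for direction in grid.directions:
        e = DIRECTION_VECTORS[direction]
        vals = np.empty((grid.n_per_direction, n, len(PLACEMENT_LABELS)))
        for si, delta in enumerate(grid.values_mm):
            vals[si] = d0 if delta == 0.0 else plan_dose(delta * e)
        samples[direction] = vals

    curves: dict[int, dict[tuple[str, str], CorrelationCurve]] = {}
    for di, diode in enumerate(diode_subset):
        if not keep[di]:
            continue
        per: dict[tuple[str, str], CorrelationCurve] = {}
        for direction in grid.directions:
            for pi, placement in enumerate(PLACEMENT_LABELS):
                ref = samples[direction][zero_idx, di, pi]
                if ref <= 0.0:
                    raise ValueError(
                        f"diode {diode} placement {placement}: zero reference dose"
                    )
                c = 100.0 * (samples[direction][:, di, pi] - ref) / ref
                c[zero_idx] = 0.0
                per[(direction, placement)] = CorrelationCurve(
                    diode=diode,
                    direction=direction,
                    placement=placement,
                    values_percent=tuple(float(x) for x in c),
                    grid=grid,
                )
        curves[diode] = per
    provenance = {
        "plan": plan.label,
        "n_beams": len(plan),
        "dose_source": "kernel" if dose_fn is None else "grids",
        "built": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    }
    return CurveSet(grid=grid, curves=curves, provenance=provenance)


def interpolate_curve(curve: CorrelationCurve, delta_mm: float) -> float:
    """Piecewise-linear interpolation of C at ``delta_mm``; exact at nodes.

    Extrapolation beyond the +-5 mm grid is refused.
    """
    x = curve.grid.array
    if delta_mm < x[0] or delta_mm > x[-1]:
        raise ValueError(
            f"shift {delta_mm} mm outside the sampled range [{x[0]}, {x[-1]}] mm"
        )
    return float(np.interp(delta_mm, x, curve.array))


def invert_curve(curve: CorrelationCurve, rpd_percent: float) -> tuple[float, bool]:
    """Solve ``C(delta) = rpd`` on the piecewise-linear interpolant.

    Returns ``(delta_mm, solvable)``.  Among multiple roots the one of
    smallest magnitude wins, ties broken toward the negative root.  With no
    root, the grid shift minimising ``|C - rpd|`` is returned flagged
    ``solvable=False`` (off-node minima of a piecewise-linear function lie
    at nodes unless a segment crosses the level, which would be a root).
    """
    x = curve.grid.array
    y = curve.array
    roots: list[float] = []
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        lo, hi = (y0, y1) if y0 <= y1 else (y1, y0)
        if lo <= rpd_percent <= hi:
            if y0 == y1:
                # whole segment at the level: nearest-to-zero point of it
                roots.append(float(np.clip(0.0, x[i], x[i + 1])))
            else:
                t = (rpd_percent - y0) / (y1 - y0)
                roots.append(float(x[i] + t * (x[i + 1] - x[i])))
    if roots:
        best = min(roots, key=lambda r: (abs(r), r))
        return best, True
    resid = np.abs(y - rpd_percent)
    # No root: the level is outside the curve's range, which means the
    # measured difference is unrealistically large for this direction.  On
    # residual ties, prefer the larger-|delta| node so flat directions
    # surface as implausibly big shifts that the cross-direction minimum
    # then discards.
    order = sorted(range(len(x)), key=lambda i: (resid[i], -abs(x[i]), x[i]))
    return float(x[order[0]]), False


def min_direction_error(
    curves: Mapping[str, CorrelationCurve], rpd_percent: float
) -> tuple[float, str, float, bool]:
    """Invert the three direction curves and keep the smallest-|delta| result.

    Directions with flat curves map a given dose difference to implausibly
    large shifts; taking the minimum across directions discards them.
    Returns ``(|delta|, direction, signed delta, solvable)``; the selection
    is invariant under permutation of the input order.
    """
    if set(curves) != set(DIRECTIONS):
        raise ValueError(f"exactly the three direction curves required, got {set(curves)}")
    results = []
    for direction in sorted(curves):
        delta, solvable = invert_curve(curves[direction], rpd_percent)
        results.append((not solvable, abs(delta), delta, direction, solvable))
    # a direction with an actual root always beats a flagged minimizer:
    # only when no direction can reproduce the measured difference does a
    # flagged value survive into the report
    results.sort(key=lambda r: r[:4])
    _, abs_d, delta, direction, solvable = results[0]
    return abs_d, direction, delta, solvable
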