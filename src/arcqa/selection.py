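"""Beam-to-diode matching: which diode monitors which beam.

Each beam of the QA plan is matched to at most one diode so a per-diode
dose difference can be attributed to a per-beam position error:

* per beam, among diodes whose single-beam signal reaches the selection
  threshold (default 10% of the maximum single-diode signal), the diode
  with the maximum signal is the candidate;
* a diode that responds above threshold to two or more beams is excluded
  outright — its dose difference would mix pointing errors of several
  beams;
* entries whose diode also receives appreciable dose (a fraction of its
  matched beam's signal) from a beam opposing its matched beam within an
  angular tolerance are removed, since opposing beams cancel out or
  exaggerate the inverted error.

Every exclusion is logged with its reason so a selection can be audited
and reproduced from the signals alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dose_model import ConeKernel, DoseVector, beam_dose_at_points, PhantomCylinder
from .geometry import DiodeArray
from .plan_model import QAPlan, opposing_pairs

__all__ = [
    "BeamDiodeLUT",
    "Exclusion",
    "per_beam_signals",
    "build_beam_diode_lut",
    "exclude_opposing",
]


@dataclass(frozen=True)
class Exclusion:
    """One logged selection decision."""

    reason: str  # multi-beam | sub-threshold | opposing-pair | no-signal
    beam: int | None = None
    diode: int | None = None


@dataclass
class BeamDiodeLUT:
    """Map beam id -> monitoring diode index, with an exclusion audit log."""

    mapping: dict[int, int]
    exclusions: tuple[Exclusion, ...] = ()
    threshold: float = 0.0
    threshold_reference: str = "global"

    def __post_init__(self) -> None:
        diodes = list(self.mapping.values())
        if len(diodes) != len(set(diodes)):
            raise ValueError("each selected diode may monitor exactly one beam")

    @property
    def diodes(self) -> list[int]:
        return sorted(self.mapping.values())

    def beam_of(self, diode: int) -> int:
        for b, d in self.mapping.items():
            if d == diode:
                return b
        raise KeyError(f"diode {diode} is not in the LUT")

    def __len__(self) -> int:
        return len(self.mapping)


def per_beam_signals(
    plan: QAPlan, array: DiodeArray, kernel: ConeKernel
) -> dict[int, DoseVector]:
    """Noise-free dose vector of each individual beam (deterministic).

    By linearity these sum to the full-plan delivery vector; they replace
    the physical beam-by-beam movie-file synchronisation.
    """
    cylinder = PhantomCylinder(radius_mm=array.radius_mm)
    out: dict[int, DoseVector] = {}
    for beam in plan:
        vals = beam_dose_at_points(beam, array.positions, kernel, cylinder)
        out[beam.beam_id] = DoseVector(values=vals, label=f"beam-{beam.beam_id}")
    return out


def build_beam_diode_lut(
    signals: Mapping[int, DoseVector],
    threshold_fraction: float = 0.10,
    threshold_reference: str = "global",
) -> BeamDiodeLUT:
    """Apply the selection criteria to per-beam signal maps.

    ``threshold_reference`` picks what the threshold fraction refers to:
    ``"global"`` (default) — the maximum single-diode signal over all
    beams; ``"per-beam"`` — each beam's own maximum diode signal.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold fraction must be in (0, 1)")
    if threshold_reference not in ("global", "per-beam"):
        raise ValueError("threshold reference must be 'global' or 'per-beam'")
    if not signals:
        return BeamDiodeLUT(mapping={}, threshold=0.0, threshold_reference=threshold_reference)

    beam_ids = sorted(signals)
    stack = {b: np.asarray(signals[b].values, dtype=float) for b in beam_ids}
    global_max = max((float(v.max()) for v in stack.values()), default=0.0)
    global_threshold = threshold_fraction * global_max

    exclusions: list[Exclusion] = []
    responders: dict[int, np.ndarray] = {}
    for b in beam_ids:
        v = stack[b]
        thr = (
            global_threshold
            if threshold_reference == "global"
            else threshold_fraction * float(v.max())
        )
        responders[b] = np.flatnonzero(v >= thr) if v.max() > 0 else np.array([], dtype=int)

    # criterion (b): a diode with above-threshold signal from >= 2 beams is out
    counts: dict[int, list[int]] = {}
    for b in beam_ids:
        for d in responders[b]:
            counts.setdefault(int(d), []).append(b)
    multi = {d for d, bs in counts.items() if len(bs) >= 2}
    for d in sorted(multi):
        for b in counts[d]:
            exclusions.append(Exclusion(reason="multi-beam", beam=b, diode=d))

    mapping: dict[int, int] = {}
    for b in beam_ids:
        v = stack[b]
        if v.max() <= 0:
            exclusions.append(Exclusion(reason="no-signal", beam=b))
            continue
        if len(responders[b]) == 0:
            exclusions.append(Exclusion(reason="sub-threshold", beam=b))
            continue
        candidates = [int(d) for d in responders[b] if int(d) not in multi]
        if not candidates:
            # all its responders were shared with other beams
            continue
        mapping[b] = max(candidates, key=lambda d: (v[d], -d))
    lut = BeamDiodeLUT(
        mapping=mapping,
        exclusions=tuple(exclusions),
        threshold=global_threshold,
        threshold_reference=threshold_reference,
    )
    return lut


def exclude_opposing(
    lut: BeamDiodeLUT,
    plan: QAPlan,
    signals: Mapping[int, DoseVector],
    angle_tol_deg: float = 5.0,
    contamination_fraction: float = 0.10,
) -> BeamDiodeLUT:
    """Drop LUT entries whose diode is also irradiated by an opposing beam.

    An entry (beam b -> diode d) is removed when any beam closely opposing
    b (within ``angle_tol_deg``) deposits at least
    ``contamination_fraction`` of b's own signal at d.  The bar is relative
    to the matched beam's signal (not the global selection threshold):
    the multi-beam criterion already removes diodes that respond above the
    selection threshold to two beams, so this filter exists to catch the
    weaker exit-dose contamination an opposing beam leaves on an entrance
    diode.  The result is always a subset of the input LUT.
    """
    pairs = opposing_pairs(plan, angle_tol_deg)
    opposed: dict[int, set[int]] = {}
    for pair in pairs:
        a, b = tuple(pair)
        opposed.setdefault(a, set()).add(b)
        opposed.setdefault(b, set()).add(a)
    mapping = dict(lut.mapping)
    exclusions = list(lut.exclusions)
    for b, d in sorted(lut.mapping.items()):
        own = signals[b].values[d]
        for other in sorted(opposed.get(b, ())):
            if other in signals and signals[other].values[d] >= contamination_fraction * own:
                del mapping[b]
                exclusions.append(Exclusion(reason="opposing-pair", beam=b, diode=d))
                break
    return BeamDiodeLUT(
        mapping=mapping,
        exclusions=tuple(exclusions),
        threshold=lut.threshold,
        threshold_reference=lut.threshold_reference,
    )
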