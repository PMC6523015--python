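"""The isocentric body-path QA plan: many small non-coplanar cone beams.

The constancy test delivers an isocentric plan of 5 mm cone beams (default
116 beams, 50 MU each) from robot nodes distributed around the phantom.
The machine's actual node set is proprietary, so a seeded quasi-uniform
sampler over an allowed source shell stands in for it: sources restricted
to a polar band measured from the vertical (+y, anterior) axis — beams
never fire up through the couch — with the source-axis distance (SAD)
drawn from a configurable range around the nominal 800 mm cone-definition
distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Beam",
    "QAPlan",
    "Workspace",
    "generate_body_path_plan",
    "opposing_pairs",
    "make_parallel_opposed_pair",
]

#: Cone nominal diameter is defined at this distance from the source (mm).
CONE_DEFINITION_DISTANCE_MM = 800.0


@dataclass(frozen=True)
class Beam:
    """A single cone beam aimed from a robot node.

    ``direction`` is the unit vector from source toward the target;
    ``cone_diameter_mm`` is the nominal field diameter at 800 mm from the
    source.
    """

    beam_id: int
    source: tuple[float, float, float]
    direction: tuple[float, float, float]
    cone_diameter_mm: float = 5.0
    mu: float = 50.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError(f"beam {self.beam_id}: direction must have unit norm")
        if self.mu <= 0:
            raise ValueError(f"beam {self.beam_id}: MU must be positive")
        if self.cone_diameter_mm <= 0:
            raise ValueError(f"beam {self.beam_id}: cone diameter must be positive")

    @property
    def source_array(self) -> np.ndarray:
        return np.asarray(self.source, dtype=float)

    @property
    def direction_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    def to_dict(self) -> dict:
        return {
            "id": self.beam_id,
            "source": [round(float(c), 6) for c in self.source],
            "direction": [round(float(c), 12) for c in self.direction],
            "cone_diameter_mm": self.cone_diameter_mm,
            "mu": self.mu,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Beam":
        d = np.asarray(payload["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        return cls(
            beam_id=int(payload["id"]),
            source=tuple(float(c) for c in payload["source"]),
            direction=tuple(float(c) for c in d),
            cone_diameter_mm=float(payload["cone_diameter_mm"]),
            mu=float(payload["mu"]),
        )


@dataclass(frozen=True)
class QAPlan:
    """Ordered list of beams, all aimed at a common isocenter."""

    beams: tuple[Beam, ...]
    label: str = "body-path"
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ids = [b.beam_id for b in self.beams]
        if len(ids) != len(set(ids)):
            raise ValueError("beam ids must be unique")
        iso = np.asarray(self.isocenter, dtype=float)
        for b in self.beams:
            sad = np.linalg.norm(iso - b.source_array)
            aim = b.source_array + sad * b.direction_array
            if np.linalg.norm(aim - iso) >= 1e-6:
                raise ValueError(f"beam {b.beam_id} is not aimed at the isocenter")

    def __len__(self) -> int:
        return len(self.beams)

    def __iter__(self):
        return iter(self.beams)

    def beam(self, beam_id: int) -> Beam:
        for b in self.beams:
            if b.beam_id == beam_id:
                return b
        raise KeyError(f"unknown beam id {beam_id}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "isocenter": [round(float(c), 6) for c in self.isocenter],
            "beams": [b.to_dict() for b in self.beams],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "QAPlan":
        iso = np.asarray(payload["isocenter"], dtype=float)
        beams = []
        for entry in payload["beams"]:
            b = Beam.from_dict(entry)
            # re-aim exactly at the isocenter: rounding the source in the
            # serialization would otherwise break the aiming invariant
            d = iso - b.source_array
            d = d / np.linalg.norm(d)
            beams.append(
                Beam(b.beam_id, b.source, tuple(float(c) for c in d),
                     b.cone_diameter_mm, b.mu)
            )
        return cls(
            beams=tuple(beams),
            label=str(payload["label"]),
            isocenter=tuple(float(c) for c in iso),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "QAPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Workspace:
    """Allowed source shell for body-path nodes.

    ``polar_deg`` is measured from the +z (SI) axis; the default band
    [60, 120] keeps sources within +-30 degrees of the axial plane, so
    beams are predominantly laterally oriented, as a body path around a
    supine patient is.  ``azimuth_deg`` is measured in the x-y plane from
    +x toward +y; the default [-10, 190] keeps sources in the upper
    half-space (never firing up through the couch, allowing a 10-degree
    dip below the horizontal).  ``sad_mm`` bounds the source-to-isocenter
    distance around the nominal 800 mm cone-definition distance.
    """

    polar_deg: tuple[float, float] = (60.0, 120.0)
    azimuth_deg: tuple[float, float] = (-10.0, 190.0)
    sad_mm: tuple[float, float] = (700.0, 900.0)

    def __post_init__(self) -> None:
        if not (0 <= self.polar_deg[0] < self.polar_deg[1] <= 180):
            raise ValueError("polar band must be a non-empty range within [0, 180] deg")
        if self.azimuth_deg[0] >= self.azimuth_deg[1]:
            raise ValueError("azimuth range must be non-empty")
        if not (0 < self.sad_mm[0] <= self.sad_mm[1]):
            raise ValueError("SAD range must be positive and non-empty")
        if not (650.0 <= self.sad_mm[0] and self.sad_mm[1] <= 1000.0):
            raise ValueError("SAD range must lie within [650, 1000] mm")


def generate_body_path_plan(
    n_beams: int = 116,
    seed: int = 0,
    workspace: Workspace | None = None,
    isocenter: Sequence[float] = (0.0, 0.0, 0.0),
    cone_diameter_mm: float = 5.0,
    mu: float = 50.0,
    label: str = "body-path",
) -> QAPlan:
    """Seeded quasi-uniform body-path plan, all beams aimed at the isocenter.

    Sources are drawn uniformly (by area) over the workspace's spherical
    band about the +y axis, at SADs uniform in the workspace range.  The
    same seed reproduces the identical plan bit-for-bit.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    ws = workspace or Workspace()
    rng = np.random.default_rng(seed)
    iso = np.asarray(isocenter, dtype=float)

    lo, hi = np.cos(np.deg2rad(ws.polar_deg[1])), np.cos(np.deg2rad(ws.polar_deg[0]))
    cos_polar = rng.uniform(lo, hi, size=n_beams)  # uniform by band area
    azim = np.deg2rad(rng.uniform(*ws.azimuth_deg, size=n_beams))
    sad = rng.uniform(*ws.sad_mm, size=n_beams)

    sin_polar = np.sqrt(1.0 - cos_polar**2)
    # unit vector from isocenter toward the source; polar from +z (SI)
    u = np.column_stack(
        [sin_polar * np.cos(azim), sin_polar * np.sin(azim), cos_polar]
    )
    beams = []
    for i in range(n_beams):
        src = iso + sad[i] * u[i]
        d = (iso - src) / np.linalg.norm(iso - src)
        beams.append(
            Beam(
                beam_id=i,
                source=tuple(float(c) for c in src),
                direction=tuple(float(c) for c in d),
                cone_diameter_mm=cone_diameter_mm,
                mu=mu,
            )
        )
    return QAPlan(beams=tuple(beams), label=label, isocenter=tuple(float(c) for c in iso))


def opposing_pairs(plan: QAPlan, angle_tol_deg: float = 5.0) -> set[frozenset[int]]:
    """Unordered pairs of beams that are opposing or closely opposing.

    A pair (i, j) qualifies when the angle between ``d_i`` and ``-d_j`` is
    at most ``angle_tol_deg``.  Such beams share an entrance/exit geometry
    that can cancel out or exaggerate an inverted position error.
    """
    if not (0 < angle_tol_deg <= 30):
        raise ValueError("angle tolerance must be in (0, 30] degrees")
    dirs = np.array([b.direction_array for b in plan.beams])
    ids = [b.beam_id for b in plan.beams]
    cos_tol = math.cos(math.radians(angle_tol_deg))
    dots = -dirs @ dirs.T  # cos(angle(d_i, -d_j))
    pairs: set[frozenset[int]] = set()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dots[i, j] >= cos_tol - 1e-12:
                pairs.add(frozenset((ids[i], ids[j])))
    return pairs


def make_parallel_opposed_pair(
    sad_mm: float = 800.0, axis: Sequence[float] = (1.0, 0.0, 0.0), mu: float = 200.0
) -> QAPlan:
    """Two-beam fixture: parallel-opposed beams along ``axis`` (for tests)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    beams = (
        Beam(0, tuple(sad_mm * a), tuple(-a), cone_diameter_mm=5.0, mu=mu),
        Beam(1, tuple(-sad_mm * a), tuple(a), cone_diameter_mm=5.0, mu=mu),
    )
    return QAPlan(beams=beams, label="parallel-opposed")
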