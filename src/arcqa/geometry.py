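"""Cylindrical diode-array geometry and the shared patient coordinate frame.

The detector is a helical lattice of diodes on the surface of a cylinder
(1386 diodes, 21 cm diameter x 21 cm length, ~1 cm nearest-neighbour
spacing).  All positions are expressed in a right-handed patient frame with
its origin at the array's geometric centre (the alignment centre):

* LR (left-right)        -> +x, toward patient left
* AP (antero-posterior)  -> +y, toward anterior
* SI (supero-inferior)   -> +z, toward superior

The vendor's exact diode layout is proprietary; a single-start helix is used
as a surrogate that preserves everything the analysis depends on: diode
count, cylindrical shell, and ~10 mm detector spacing.

Each diode also carries seven *placement hypotheses* reflecting its stated
0.5 mm placement accuracy: the nominal lattice position plus +-0.5 mm along
each axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "AXIS_INDEX",
    "DIRECTION_VECTORS",
    "DIRECTIONS",
    "PLACEMENT_LABELS",
    "DiodeArray",
    "PatientFrame",
    "PlacementOffset",
    "build_arccheck_geometry",
    "diode_position",
    "enumerate_placements",
]

#: Clinical direction labels in canonical order.
DIRECTIONS: tuple[str, ...] = ("AP", "SI", "LR")

#: Unit vectors of the clinical directions in the patient frame.
DIRECTION_VECTORS: dict[str, np.ndarray] = {
    "LR": np.array([1.0, 0.0, 0.0]),
    "AP": np.array([0.0, 1.0, 0.0]),
    "SI": np.array([0.0, 0.0, 1.0]),
}

#: Axis (column) index of each clinical direction.
AXIS_INDEX: dict[str, int] = {"LR": 0, "AP": 1, "SI": 2}

#: Placement-hypothesis labels, nominal first, then +-0.5 mm per axis.
PLACEMENT_LABELS: tuple[str, ...] = ("nominal", "+x", "-x", "+y", "-y", "+z", "-z")

_PLACEMENT_VECTORS: dict[str, np.ndarray] = {
    "nominal": np.zeros(3),
    "+x": np.array([0.5, 0.0, 0.0]),
    "-x": np.array([-0.5, 0.0, 0.0]),
    "+y": np.array([0.0, 0.5, 0.0]),
    "-y": np.array([0.0, -0.5, 0.0]),
    "+z": np.array([0.0, 0.0, 0.5]),
    "-z": np.array([0.0, 0.0, -0.5]),
}


@dataclass(frozen=True)
class PatientFrame:
    """Right-handed patient coordinate frame shared by all modules."""

    convention: str = "LR=+x, AP=+y, SI=+z; origin at array centre; mm"
    axes: dict = field(
        default_factory=lambda: {"LR": 0, "AP": 1, "SI": 2}
    )

    def __post_init__(self) -> None:
        labels = set(self.axes)
        cols = set(self.axes.values())
        if labels != {"LR", "AP", "SI"} or cols != {0, 1, 2}:
            raise ValueError("direction labels must map bijectively onto the three axes")


@dataclass(frozen=True)
class PlacementOffset:
    """One of the seven candidate true positions of a diode.

    The offset is either zero (nominal) or exactly 0.5 mm along a single
    patient-frame axis, matching the stated diode placement accuracy.
    """

    diode: int
    label: str
    vector: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        norm = float(np.linalg.norm(v))
        on_axis = np.count_nonzero(v) <= 1
        if not (on_axis and (norm == 0.0 or abs(norm - 0.5) < 1e-12)):
            raise ValueError(
                f"placement offset must be 0 or 0.5 mm along one axis, got {self.vector}"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


@dataclass(frozen=True)
class DiodeArray:
    """Helical lattice of diodes on a cylinder surface.

    Attributes
    ----------
    radius_mm, length_mm:
        Cylinder radius and axial length in mm.
    positions:
        ``(count, 3)`` Cartesian diode positions in the patient frame; diode
        ``k`` is row ``k``.
    """

    radius_mm: float
    length_mm: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n>=2, 3) array")
        object.__setattr__(self, "positions", pos)
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("cylinder radius and length must be positive")
        radial = np.hypot(pos[:, 0], pos[:, 1])
        if np.max(np.abs(radial - self.radius_mm)) >= 1e-9:
            raise ValueError("every diode must lie on the cylinder surface")
        half = self.length_mm / 2 + 1e-9
        if np.any(np.abs(pos[:, 2]) > half):
            raise ValueError("diode z coordinates must lie within the cylinder length")

    @property
    def count(self) -> int:
        return int(self.positions.shape[0])

    @property
    def helix_angles(self) -> np.ndarray:
        """Helix angle of each diode in radians (continuous, unwrapped)."""
        return np.unwrap(np.arctan2(self.positions[:, 1], self.positions[:, 0]))

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "radius_mm": self.radius_mm,
            "length_mm": self.length_mm,
            "positions": [[round(float(c), 6) for c in row] for row in self.positions],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiodeArray":
        pos = np.asarray(payload["positions"], dtype=float)
        if pos.shape[0] != payload["count"]:
            raise ValueError("diode count does not match position rows")
        radius = float(payload["radius_mm"])
        # snap the 6-decimal serialized coordinates back onto the cylinder
        radial = np.hypot(pos[:, 0], pos[:, 1])
        if np.max(np.abs(radial - radius)) > 1e-3:
            raise ValueError("positions stray too far from the cylinder surface")
        pos = pos.copy()
        pos[:, :2] *= (radius / radial)[:, None]
        return cls(
            radius_mm=radius,
            length_mm=float(payload["length_mm"]),
            positions=pos,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiodeArray":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_arccheck_geometry(
    count: int = 1386,
    radius_mm: float = 105.0,
    length_mm: float = 210.0,
    target_spacing_mm: float = 10.0,
) -> DiodeArray:
    """Build the surrogate helical diode lattice.

    Diode ``k`` sits at axial position ``z_k = -L/2 + k * L/(count-1)`` and
    helix angle ``theta_k = k * dtheta``, with ``dtheta`` chosen so the
    nearest-neighbour spacing along the helix is ``target_spacing_mm``
    (default 10 mm, the detector's ~1 cm resolution).  Deterministic; no
    randomness.
    """
    if count < 2:
        raise ValueError("count must be >= 2")
    if radius_mm <= 0 or length_mm <= 0 or target_spacing_mm <= 0:
        raise ValueError("radius, length and spacing must be positive")
    dz = length_mm / (count - 1)
    # chord between consecutive diodes: sqrt(dz^2 + (2 R sin(dtheta/2))^2);
    # when the axial pitch alone reaches the target spacing (tiny counts)
    # the helix degenerates to a straight axial line
    chord_sq = max(target_spacing_mm**2 - dz**2, 0.0)
    dtheta = 2.0 * math.asin(min(1.0, math.sqrt(chord_sq) / (2.0 * radius_mm)))
    k = np.arange(count)
    theta = k * dtheta
    z = -length_mm / 2 + k * dz
    positions = np.column_stack(
        [radius_mm * np.cos(theta), radius_mm * np.sin(theta), z]
    )
    return DiodeArray(radius_mm=radius_mm, length_mm=length_mm, positions=positions)


def enumerate_placements(index: int) -> list[PlacementOffset]:
    """The seven placement hypotheses of diode ``index``, nominal first."""
    if index < 0:
        raise KeyError(f"unknown diode index {index}")
    return [
        PlacementOffset(diode=index, label=lab, vector=tuple(_PLACEMENT_VECTORS[lab]))
        for lab in PLACEMENT_LABELS
    ]


def placement_vector(label: str) -> np.ndarray:
    """Offset vector (mm) of a placement-hypothesis label."""
    try:
        return _PLACEMENT_VECTORS[label].copy()
    except KeyError:
        raise KeyError(f"unknown placement label {label!r}") from None


def diode_position(
    array: DiodeArray, index: int, placement: PlacementOffset | str | None = None
) -> np.ndarray:
    """Cartesian position of a diode under a placement hypothesis."""
    if not 0 <= index < array.count:
        raise KeyError(f"unknown diode index {index}")
    pos = array.positions[index].copy()
    if placement is None:
        return pos
    if isinstance(placement, str):
        return pos + placement_vector(placement)
    if placement.diode != index:
        raise KeyError(
            f"placement belongs to diode {placement.diode}, not {index}"
        )
    return pos + placement.array
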