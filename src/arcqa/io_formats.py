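"""Readers and writers for every artifact the pipeline touches.

A versioned plain-text measurement dialect stands in for the vendor's
measurement export (the method only needs per-diode dose values with a
little provenance).  Dose grids travel either in a JSON container or as
DICOM RT Dose objects read through pydicom; both produce the same
in-memory grid.  Curve sets, lookup tables and reports persist as JSON /
CSV.  All writers are deterministic: identical inputs yield byte-identical
files (sorted keys, fixed six-decimal float formatting).

File extensions: ``.acmeas.txt`` (measurement), ``.dosegrid.json`` / ``.dcm``
(grids), ``.curves.json``, ``.lut.json``, ``.report.csv`` / ``.summary.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
import numpy as np

from .analysis import PlacementLUT, PositionErrorReport
from .correlation import CorrelationCurve, CurveSet, ShiftGrid
from .dose_model import DoseGrid, DoseVector
from .geometry import PLACEMENT_LABELS
from .selection import BeamDiodeLUT, Exclusion

logger = logging.getLogger(__name__)

__all__ = [
    "read_measurement",
    "write_measurement",
    "read_dose_grid",
    "write_dose_grid",
    "read_dicom_rt_dose",
    "save_curves",
    "load_curves",
    "save_lut",
    "load_lut",
    "save_placement_lut",
    "load_placement_lut",
    "write_report",
]

MEASUREMENT_MAGIC = "# arcqa-measurement"
MEASUREMENT_VERSION = 1


class ParseError(ValueError):
    """Malformed pipeline artifact file."""


def write_measurement(
    vector: DoseVector,
    path: str | Path,
    plan_id: str = "",
    timestamp: str = "",
) -> None:
    """Write a per-diode dose vector in the measurement text dialect."""
    lines = [
        f"{MEASUREMENT_MAGIC} v{MEASUREMENT_VERSION}",
        f"# label: {vector.label}",
        f"# timestamp: {timestamp}",
        f"# plan: {plan_id}",
        f"# diodes: {len(vector)}",
    ]
    for i, v in enumerate(vector.values):
        lines.append(f"{i} {v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurement(path: str | Path) -> DoseVector:
    """Read a measurement file; strict header validation.

    Rows may arrive out of index order (re-sorted with a warning); a
    wrong row count, a negative dose or an unknown format version raise
    parse errors naming the offending line.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(MEASUREMENT_MAGIC):
        raise ParseError(f"{path}: line 1: not a measurement file")
    version = lines[0].removeprefix(MEASUREMENT_MAGIC).strip()
    if version != f"v{MEASUREMENT_VERSION}":
        raise ParseError(f"{path}: line 1: unknown format version {version!r}")
    header: dict[str, str] = {}
    body_start = 1
    for ln, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            body_start = ln
            break
        key, _, val = line.lstrip("# ").partition(":")
        header[key.strip()] = val.strip()
    else:
        body_start = len(lines) + 1
    try:
        count = int(header["diodes"])
    except (KeyError, ValueError):
        raise ParseError(f"{path}: header is missing a valid 'diodes' count") from None
    rows: list[tuple[int, float]] = []
    for ln, line in enumerate(lines[body_start - 1 :], start=body_start):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: line {ln}: expected 'index dose', got {line!r}")
        try:
            idx, dose = int(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(f"{path}: line {ln}: malformed row {line!r}") from None
        if dose < 0:
            raise ParseError(f"{path}: line {ln}: negative dose {dose}")
        rows.append((idx, dose))
    if len(rows) != count:
        raise ParseError(
            f"{path}: expected {count} diode rows, found {len(rows)}"
        )
    indices = [r[0] for r in rows]
    if sorted(indices) != list(range(count)):
        raise ParseError(f"{path}: diode indices are not 0..{count - 1}")
    if indices != sorted(indices):
        logger.warning("%s: diode rows out of order; re-sorted", path)
        rows.sort(key=lambda r: r[0])
    return DoseVector(
        values=np.array([r[1] for r in rows]), label=header.get("label", "")
    )


# ---------------------------------------------------------------------------
# Dose grids


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    payload = {
        "version": 1,
        "dimensions": list(grid.shape),
        "origin_mm": [float(c) for c in grid.origin],
        "spacing_mm": [float(c) for c in grid.spacing],
        "axis_order": "xyz",
        "scale": 1.0,
        "values": [round(float(v), 6) for v in grid.values.ravel(order="C")],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_dose_grid(path: str | Path) -> DoseGrid:
    """Read the JSON dose-grid container."""
    payload = json.loads(Path(path).read_text())
    for key in ("dimensions", "origin_mm", "spacing_mm", "values"):
        if key not in payload:
            raise ParseError(f"{path}: dose grid is missing {key!r}")
    dims = tuple(int(n) for n in payload["dimensions"])
    spacing = tuple(float(s) for s in payload["spacing_mm"])
    if any(s <= 0 for s in spacing):
        raise ParseError(f"{path}: non-positive grid spacing {spacing}")
    if payload.get("axis_order", "xyz") != "xyz":
        raise ParseError(f"{path}: unsupported axis_order {payload.get('axis_order')!r}")
    values = np.asarray(payload["values"], dtype=float)
    if values.size != int(np.prod(dims)):
        raise ParseError(
            f"{path}: payload length {values.size} != product of dimensions {dims}"
        )
    scale = float(payload.get("scale", 1.0))
    return DoseGrid(
        origin=tuple(float(c) for c in payload["origin_mm"]),
        spacing=spacing,
        values=scale * values.reshape(dims, order="C"),
    )


def read_dicom_rt_dose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose object into the internal grid type.

    Only axis-aligned single-volume dose objects are supported (identity
    orientation, uniform frame spacing); grid scaling is applied.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    for attr in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector"):
        if getattr(ds, attr, None) is None:
            raise ParseError(f"{path}: DICOM dose is missing {attr}")
    orientation = [float(v) for v in getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(orientation, [1, 0, 0, 0, 1, 0]):
        raise ParseError(
            f"{path}: unsupported ImageOrientationPatient {orientation} (axis-aligned only)"
        )
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) == 0 or not np.allclose(dz, dz[0]) or dz[0] <= 0:
        raise ParseError(f"{path}: GridFrameOffsetVector is not uniformly increasing")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    values = np.transpose(frames, (2, 1, 0))  # -> (x, y, z)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(
        origin=origin,
        spacing=(col_spacing, row_spacing, float(dz[0])),
        values=values,
    )


# ---------------------------------------------------------------------------
# Curve sets, lookup tables, reports

CURVES_VERSION = 1
LUT_VERSION = 1


def save_curves(curves: CurveSet, path: str | Path) -> None:
    payload = {
        "version": CURVES_VERSION,
        "shift_grid_mm": list(curves.grid.values_mm),
        "directions": list(curves.grid.directions),
        "provenance": curves.provenance,
        "curves": {
            str(diode): {
                f"{direction}|{placement}": [
                    round(float(v), 6)
                    for v in curves.curves[diode][(direction, placement)].values_percent
                ]
                for direction in curves.grid.directions
                for placement in PLACEMENT_LABELS
            }
            for diode in curves.diodes
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_curves(path: str | Path) -> CurveSet:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != CURVES_VERSION:
        raise ParseError(
            f"{path}: curve schema version {payload.get('version')!r} != "
            f"{CURVES_VERSION}; no migration available"
        )
    grid = ShiftGrid(
        values_mm=tuple(payload["shift_grid_mm"]),
        directions=tuple(payload["directions"]),
    )
    curves: dict[int, dict[tuple[str, str], CorrelationCurve]] = {}
    for diode_str, entries in payload["curves"].items():
        diode = int(diode_str)
        per: dict[tuple[str, str], CorrelationCurve] = {}
        for key, values in entries.items():
            direction, _, placement = key.partition("|")
            per[(direction, placement)] = CorrelationCurve(
                diode=diode,
                direction=direction,
                placement=placement,
                values_percent=tuple(float(v) for v in values),
                grid=grid,
            )
        curves[diode] = per
    return CurveSet(grid=grid, curves=curves, provenance=payload.get("provenance", {}))


def _reject_duplicate_keys(pairs):
    seen = {}
    for k, v in pairs:
        if k in seen:
            raise ParseError(f"duplicate key {k!r} in JSON object")
        seen[k] = v
    return seen


def save_lut(lut: BeamDiodeLUT, path: str | Path) -> None:
    payload = {
        "version": LUT_VERSION,
        "threshold": round(float(lut.threshold), 9),
        "threshold_reference": lut.threshold_reference,
        "mapping": {str(b): int(d) for b, d in sorted(lut.mapping.items())},
        "exclusions": [
            {"reason": e.reason, "beam": e.beam, "diode": e.diode}
            for e in lut.exclusions
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_lut(path: str | Path) -> BeamDiodeLUT:
    payload = json.loads(Path(path).read_text(), object_pairs_hook=_reject_duplicate_keys)
    if payload.get("version") != LUT_VERSION:
        raise ParseError(
            f"{path}: LUT schema version {payload.get('version')!r} != "
            f"{LUT_VERSION}; no migration available"
        )
    return BeamDiodeLUT(
        mapping={int(b): int(d) for b, d in payload["mapping"].items()},
        exclusions=tuple(
            Exclusion(reason=e["reason"], beam=e.get("beam"), diode=e.get("diode"))
            for e in payload.get("exclusions", [])
        ),
        threshold=float(payload["threshold"]),
        threshold_reference=payload["threshold_reference"],
    )


def save_placement_lut(plut: PlacementLUT, path: str | Path) -> None:
    payload = {
        "version": LUT_VERSION,
        "placements": {str(d): p for d, p in sorted(plut.placements.items())},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_placement_lut(path: str | Path) -> PlacementLUT:
    payload = json.loads(Path(path).read_text(), object_pairs_hook=_reject_duplicate_keys)
    if payload.get("version") != LUT_VERSION:
        raise ParseError(f"{path}: placement-LUT schema version mismatch")
    return PlacementLUT(
        placements={int(d): str(p) for d, p in payload["placements"].items()}
    )


def write_report(
    report: PositionErrorReport, csv_path: str | Path, summary_path: str | Path | None = None
) -> None:
    """Write the per-diode table as CSV and the summary as JSON."""
    report.table.to_csv(csv_path, index=False, float_format="%.6f")
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(report.summary, sort_keys=True))
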