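"""Run configuration: one serialisable record of every tunable parameter.

Analysis outputs embed the configuration's hash so any report can be traced
back to the exact geometry, plan, kernel, selection and noise settings that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dose_model import ConeKernel
from .plan_model import Workspace
from .simulator import NoiseModel

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # geometry
    diode_count: int = 1386
    cylinder_radius_mm: float = 105.0
    cylinder_length_mm: float = 210.0
    # plan
    n_beams: int = 116
    plan_seed: int = 0
    workspace: Workspace = field(default_factory=Workspace)
    # dose kernel
    kernel: ConeKernel = field(default_factory=ConeKernel)
    # selection
    threshold_fraction: float = 0.10
    threshold_reference: str = "global"
    opposing_tol_deg: float = 5.0
    # analysis
    margin_percent: float = 1.0
    # simulation
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_baseline: int = 6
    n_same_day: int = 5
    n_null_seeds: int = 100

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (int, float, str, bool)) or obj is None:
                return obj
            return float(obj)

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "workspace" in payload:
            ws = payload["workspace"]
            payload["workspace"] = Workspace(
                polar_deg=tuple(ws["polar_deg"]),
                azimuth_deg=tuple(ws["azimuth_deg"]),
                sad_mm=tuple(ws["sad_mm"]),
            )
        if "kernel" in payload:
            payload["kernel"] = ConeKernel(**payload["kernel"])
        if "noise" in payload:
            payload["noise"] = NoiseModel(**payload["noise"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
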