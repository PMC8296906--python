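"""Run configuration: one YAML file drives a full post-processing run.

Defaults carry the physiological constants used throughout: blood density
1060 kg/m^3, dynamic viscosity 0.004 Pa.s, cardiac period 0.8 s sampled at
0.01 s.  Mesh coordinates in mm are converted by ``length_scale: 1e-3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import FluidProperties, ValidationError
from .segmentation import PlaneSpec

__all__ = ["RunConfig"]


def _plane(d: dict, label: str) -> PlaneSpec:
    return PlaneSpec.from_vectors(d["origin"], d["normal"], d.get("label", label))


@dataclass
class RunConfig:
    manifest: str | None = None
    output_dir: str = "out"
    density: float = 1060.0
    dynamic_viscosity: float = 0.004
    gradient_scheme: str = "wlsq"
    period: float = 0.8
    step: float = 0.01
    n_cycles: int = 1
    t0: float | None = None
    length_scale: float = 1.0
    seed: int = 0
    velocity_name: str = "velocity"
    pressure_name: str = "pressure"
    mass_balance_tol: float = 0.02
    bernoulli_kinetic: str = "mean_velocity"
    segment_planes: tuple | None = None  # (inlet_end, outlet_start) PlaneSpec
    cut_planes: dict = field(default_factory=dict)  # label -> PlaneSpec
    sections: dict = field(default_factory=dict)  # name -> {origin, normal, radius}
    synth: dict = field(default_factory=dict)  # generator parameters

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("density and viscosity must be positive")
        if self.period <= 0 or self.step <= 0 or self.step > self.period:
            raise ValidationError("need 0 < step <= period")
        if self.gradient_scheme not in ("wlsq", "green_gauss", "structured"):
            raise ValidationError(f"unknown gradient scheme {self.gradient_scheme!r}")

    @property
    def props(self) -> FluidProperties:
        return FluidProperties(self.density, self.dynamic_viscosity)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = raw.pop("segments", None)
        planes = raw.pop("planes", {})
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(kwargs)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        if seg:
            cfg.segment_planes = (
                _plane(seg["inlet_end"], "segment-boundary"),
                _plane(seg["outlet_start"], "segment-boundary"),
            )
        cfg.cut_planes = {k: _plane(v, k) for k, v in planes.items()}
        return cfg

    def validate_paths(self) -> None:
        if self.manifest is not None and not Path(self.manifest).exists():
            raise ValidationError(f"manifest not found: {self.manifest}")
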