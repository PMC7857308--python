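"""Pipeline configuration: YAML-backed, validated, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if hasattr(f.type, "__dataclass_fields__") or f.name in _NESTED:
                v = _build(_NESTED[f.name], v, f"{path}.{f.name}")
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SynthBlock:
    seed: int = 1
    marker_rate: float = 120.0
    force_rate: float = 2000.0
    marker_noise_std: float = 0.001          # m
    sta_amplitude: float = 0.003             # m
    toe_offset_deg: float = 10.0
    width_offset_m: float = 0.03
    wedge_cop_shift: float = 0.002           # m lateral CoP shift per degree
    wedge_grf_tilt: float = 0.004            # Fz fraction per degree
    n_trials: int = 3


@dataclass
class ScalingBlock:
    method: str = "both"                     # linear | mri_morph | both
    fat_slope: float = 0.01
    seedhom_c_med: float = 0.24
    seedhom_c_lat: float = 0.24


@dataclass
class KinematicsBlock:
    filter_cutoff_hz: float = 6.0
    grf_filter_cutoff_hz: float = 15.0


@dataclass
class DynamicsBlock:
    recruitment_power: int = 3
    residual_weight: float = 1000.0


@dataclass
class KneeloadsBlock:
    clamp_negative: bool = True


@dataclass
class OutcomesBlock:
    stance_threshold_n: float = 20.0
    alpha: float = 0.05
    n_comparisons: int | None = None


@dataclass
class PipelineConfig:
    output_dir: str = "results"
    synth: SynthBlock = field(default_factory=SynthBlock)
    scaling: ScalingBlock = field(default_factory=ScalingBlock)
    kinematics: KinematicsBlock = field(default_factory=KinematicsBlock)
    dynamics: DynamicsBlock = field(default_factory=DynamicsBlock)
    kneeloads: KneeloadsBlock = field(default_factory=KneeloadsBlock)
    outcomes: OutcomesBlock = field(default_factory=OutcomesBlock)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return _build(cls, data, "config")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @property
    def routes(self):
        if self.scaling.method == "both":
            return ("linear", "mri_morph")
        return (self.scaling.method,)


_NESTED = {"synth": SynthBlock, "scaling": ScalingBlock,
           "kinematics": KinematicsBlock, "dynamics": DynamicsBlock,
           "kneeloads": KneeloadsBlock, "outcomes": OutcomesBlock}
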