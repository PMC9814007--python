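"""Run configuration: YAML with explicit units in key names, unknown keys rejected."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _strict(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class GeometryConfig:
    base_radius_mm: float = 24.0
    apex_to_base_mm: float = 80.0
    cap_height_mm: float = 20.0
    n_circumferential: int = 48
    n_longitudinal: int = 32
    n_key_frames: int = 24
    edv_ml: float = 162.7
    esv_ml: float = 53.7
    cycle_duration_s: float = 0.87
    systole_fraction: float = 1.0 / 3.0
    e_peak_s: float = 0.42
    a_peak_s: float = 0.78
    e_a_ratio: float = 2.0
    resample_dt_s: float = 0.03


@dataclass
class TorsionConfig:
    enabled: bool = True
    gamma_deg: float = 13.0


@dataclass
class ValveConfig:
    enabled: bool = True
    thickness_mm: float = 2.0
    annulus_radius_mm: float = 11.0
    n_annulus_points: int = 64
    anterior_deg: float = 55.0
    posterior_deg: float = 40.0
    front_commissure_deg: float = 25.0
    posterior_commissure_deg: float = 25.0


@dataclass
class FlowConfig:
    grid_n: int = 48
    peak_e_velocity_m_s: float = 2.0
    peak_a_velocity_m_s: float = 0.7
    orifice_diameter_mm: float = 16.0
    ring_core_radius_mm: float = 4.0
    decay_time_s: float = 0.12
    inlet_pressure_mmhg: float = 7.0
    outlet_pressure_mmhg: float = 120.0
    n_cycles: int = 2
    cycle_perturbation: float = 0.0


@dataclass
class MetricsConfig:
    density_kg_m3: float = 1060.0
    viscosity_kg_m_s: float = 0.003
    velocity_bins_m_s: tuple = (0.0, 0.25, 0.5, 1.0, float("inf"))
    vorticity_bins_1_s: tuple = (0.0, 250.0, 500.0, 750.0, float("inf"))


@dataclass
class ParticlesConfig:
    n_particles: int = 4500
    n_beats: int = 2
    motility_threshold_m_s: float = 0.5
    substeps_per_frame: int = 4


@dataclass
class StatsConfig:
    n_clouds: int = 3
    cloud_radius_mm: float = 5.0
    cloud_points: int = 1000


@dataclass
class RunConfig:
    seed: int = 7
    output_dir: str = "ventriflow_out"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    torsion: TorsionConfig = field(default_factory=TorsionConfig)
    valve: ValveConfig = field(default_factory=ValveConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    particles: ParticlesConfig = field(default_factory=ParticlesConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"geometry": GeometryConfig, "torsion": TorsionConfig,
                    "valve": ValveConfig, "flow": FlowConfig, "metrics": MetricsConfig,
                    "particles": ParticlesConfig, "stats": StatsConfig}
        top = {k for k in data if k not in sections and k not in {"seed", "output_dir"}}
        if top:
            raise ValueError(f"unknown top-level config key(s): {sorted(top)}")
        kwargs = {k: data[k] for k in ("seed", "output_dir") if k in data}
        for name, scls in sections.items():
            kwargs[name] = _strict(scls, data.get(name, {}) or {}, name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed fanned out from the global seed (< 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{module}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)
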