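"""Run configuration: YAML schema with the device defaults pre-filled.

A config file is a YAML document with optional sections ``device``,
``ligand``, ``analysis``, ``synth`` and ``output_dir``; omitted fields fall
back to the laboratory defaults (the gLL geometry, VEGF at 100 ng/mL, the
20 µm motility threshold, alpha = 0.05).  Unknown keys are rejected with
their location.  An empty file yields the full default configuration.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .exceptions import ConfigError, UsageError
from .transport import GllGeometry, LigandSpec, TransportParams, TranswellGeometry


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DeviceConfig(_Section):
    kind: str = "gll"  # "gll" | "transwell"
    # two-reservoir device
    reservoir_volume_source_ul: float = 98.0
    reservoir_volume_sink_ul: float = 98.0
    channel_length_cm: float = 1.3
    hydraulic_diameter_um: float = 192.6
    cross_section_area_cm2: float | None = None
    # transwell
    top_volume_ul: float = 100.0
    bottom_volume_ul: float = 600.0
    membrane_thickness_um: float = 10.0
    pore_diameter_um: float = 8.0
    pore_density_per_cm2: float = 1.0e5
    membrane_area_cm2: float = 0.33
    tortuosity: float = 1.0

    def to_geometry(self) -> GllGeometry | TranswellGeometry:
        if self.kind == "gll":
            return GllGeometry(
                reservoir_volume_source_ul=self.reservoir_volume_source_ul,
                reservoir_volume_sink_ul=self.reservoir_volume_sink_ul,
                channel_length_cm=self.channel_length_cm,
                hydraulic_diameter_um=self.hydraulic_diameter_um,
                cross_section_area_cm2=self.cross_section_area_cm2,
            )
        if self.kind == "transwell":
            return TranswellGeometry(
                top_volume_ul=self.top_volume_ul,
                bottom_volume_ul=self.bottom_volume_ul,
                membrane_thickness_um=self.membrane_thickness_um,
                pore_diameter_um=self.pore_diameter_um,
                pore_density_per_cm2=self.pore_density_per_cm2,
                membrane_area_cm2=self.membrane_area_cm2,
                tortuosity=self.tortuosity,
            )
        raise ConfigError(f"device.kind must be 'gll' or 'transwell', got {self.kind!r}")


class LigandConfig(_Section):
    name: str = "VEGF"
    diffusivity_cm2_s: float | None = 9.0e-7
    hydrodynamic_radius_nm: float | None = None
    molecular_weight_kda: float | None = None
    source_concentration_ng_ml: float = 100.0
    temperature_k: float = 310.0
    viscosity_pa_s: float = 6.9e-4

    def to_ligand(self) -> LigandSpec:
        return LigandSpec(**self.model_dump())


class TransportConfig(_Section):
    bulk_velocity_m_s: float = 0.0
    grid_points: int = 130
    total_time_h: float = 48.0
    output_times_h: list[float] | None = None
    boundary_mode: str = "finite"

    def to_params(self) -> TransportParams:
        return TransportParams(**self.model_dump())


class AnalysisConfig(_Section):
    motile_threshold_um: float = 20.0
    motile_only: bool = True
    use_net_displacement: bool = False
    alpha: float = 0.05
    control_label: str = "C"
    reference_gene: str = "GAPDH"


class SynthConfig(_Section):
    seed: int = 0
    cells_per_device: int = 15
    devices_per_condition: int = 6
    ct_noise_sd: float = 0.0


class RunConfig(_Section):
    device: DeviceConfig = DeviceConfig()
    ligand: LigandConfig = LigandConfig()
    transport: TransportConfig = TransportConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    synth: SynthConfig = SynthConfig()
    output_dir: str = "gradlab-out"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    `path=None` (or an empty file) returns the full default configuration.
    Schema violations raise ConfigError naming the offending field.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {issues}") from exc
    # eagerly exercise the domain invariants so bad values fail at load time
    try:
        config.device.to_geometry()
        config.ligand.to_ligand()
        config.transport.to_params()
    except (UsageError, ConfigError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return config


def save_config(path: str | Path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
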