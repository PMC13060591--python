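"""Run configuration: YAML/JSON loading with validation and defaults.

Serialized keys carry their units as suffixes (``voltage_V``,
``pulse_ms``, ``pitch_um`` ...).  Unknown keys are rejected with the
offending field named; omitted fields fall back to the simulation defaults
(200 V, 10 ms, 10 pulses, 65% open channels, 100 x 100 grid, -70/-55/-200
mV, 1 ms refractory, 120 m/s, 600 channels/µm²).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .chip import ChipSpec, GridSpec, Material
from .errors import ConfigurationError
from .field import PulseProtocol
from .poration import MembraneParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_CHIP_KEYS = {
    "microchannel_width_um": "microchannel_width",
    "microchannel_depth_um": "microchannel_depth",
    "nanochannel_width_um": "nanochannel_width",
    "nanochannel_depth_um": "nanochannel_depth",
    "cone_base_um": "cone_base",
    "cone_height_um": "cone_height",
    "n_nanochannels": "n_nanochannels",
    "pitch_um": "pitch",
    "wafer_thickness_um": "wafer_thickness",
}
_GRID_KEYS = {
    "n_rows": "n_rows",
    "n_cols": "n_cols",
    "extent_x_um": "extent_x",
    "extent_y_um": "extent_y",
}
_PROTOCOL_KEYS = {
    "voltage_V": "voltage",
    "pulse_ms": "pulse_ms",
    "n_pulses": "n_pulses",
    "gap_ms": "gap_ms",
}
_MEMBRANE_KEYS = {
    "v_rest_mV": "v_rest",
    "v_ap_threshold_mV": "v_ap_threshold",
    "v_poration_threshold_mV": "v_poration_threshold",
    "refractory_ms": "refractory",
    "conduction_velocity_m_per_s": "conduction_velocity",
    "na_channel_density_per_um2": "na_channel_density",
    "coupling_radius_um": "coupling_radius",
}
_MATERIAL_KEYS = {
    "silicon_S_per_m": Material.SILICON,
    "lumen_open_S_per_m": Material.LUMEN_OPEN,
    "lumen_blocked_S_per_m": Material.LUMEN_BLOCKED,
    "reservoir_S_per_m": Material.RESERVOIR,
    "tissue_S_per_m": Material.TISSUE,
}
_TOP_KEYS = {
    "chip",
    "grid",
    "protocol",
    "membrane",
    "materials",
    "smoothing_sigma_cells",
    "open_fraction",
    "reservoir_depth_um",
    "triangular_tissue",
    "transfection_mean",
    "transfection_sd",
    "seed",
}


@dataclass
class RunConfig:
    """Fully validated configuration for one simulated treatment."""

    chip: ChipSpec = field(default_factory=ChipSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    protocol: PulseProtocol = field(default_factory=PulseProtocol)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    materials: dict[Material, float] = field(
        default_factory=lambda: {
            Material.SILICON: 1e-12,
            Material.LUMEN_OPEN: 1.4,
            Material.LUMEN_BLOCKED: 1e-12,
            Material.RESERVOIR: 1.4,
            Material.TISSUE: 0.5,
        }
    )
    smoothing_sigma_cells: float = 1.0
    open_fraction: float = 0.65
    reservoir_depth_um: float = 12.0
    triangular_tissue: bool = True
    transfection_mean: float = 0.6
    transfection_sd: float = 0.15
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "chip": {k: getattr(self.chip, v) for k, v in _CHIP_KEYS.items()},
            "grid": {k: getattr(self.grid, v) for k, v in _GRID_KEYS.items()},
            "protocol": {k: getattr(self.protocol, v) for k, v in _PROTOCOL_KEYS.items()},
            "membrane": {k: getattr(self.membrane, v) for k, v in _MEMBRANE_KEYS.items()},
            "materials": {k: self.materials[m] for k, m in _MATERIAL_KEYS.items()},
            "smoothing_sigma_cells": self.smoothing_sigma_cells,
            "open_fraction": self.open_fraction,
            "reservoir_depth_um": self.reservoir_depth_um,
            "triangular_tissue": self.triangular_tissue,
            "transfection_mean": self.transfection_mean,
            "transfection_sd": self.transfection_sd,
            "seed": self.seed,
        }


def _build_section(data: dict, keymap: dict, cls, section: str):
    kwargs = {}
    for key, value in data.items():
        if key not in keymap:
            raise ConfigurationError(f"unknown key {section}.{key}")
        kwargs[keymap[key]] = value
    try:
        return cls(**kwargs)
    except ConfigurationError as exc:
        raise ConfigurationError(f"in section {section!r}: {exc}") from exc


def _from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig()
    if "chip" in data:
        cfg.chip = _build_section(data["chip"], _CHIP_KEYS, ChipSpec, "chip")
    if "grid" in data:
        cfg.grid = _build_section(data["grid"], _GRID_KEYS, GridSpec, "grid")
    if "protocol" in data:
        cfg.protocol = _build_section(
            data["protocol"], _PROTOCOL_KEYS, PulseProtocol, "protocol"
        )
    if "membrane" in data:
        cfg.membrane = _build_section(
            data["membrane"], _MEMBRANE_KEYS, MembraneParams, "membrane"
        )
    if "materials" in data:
        mats = dict(cfg.materials)
        for key, value in data["materials"].items():
            if key not in _MATERIAL_KEYS:
                raise ConfigurationError(f"unknown key materials.{key}")
            if value < 0:
                raise ConfigurationError(f"materials.{key} must be >= 0")
            mats[_MATERIAL_KEYS[key]] = float(value)
        cfg.materials = mats
    for name in (
        "smoothing_sigma_cells",
        "open_fraction",
        "reservoir_depth_um",
        "triangular_tissue",
        "transfection_mean",
        "transfection_sd",
        "seed",
    ):
        if name in data:
            setattr(cfg, name, data[name])
    if cfg.smoothing_sigma_cells < 0:
        raise ConfigurationError("smoothing_sigma_cells must be >= 0")
    if not 0.0 <= cfg.open_fraction <= 1.0:
        raise ConfigurationError("open_fraction must lie in [0, 1]")
    if not 0.0 <= cfg.transfection_mean <= 1.0:
        raise ConfigurationError("transfection_mean must lie in [0, 1]")
    if cfg.transfection_sd < 0:
        raise ConfigurationError("transfection_sd must be >= 0")
    if cfg.reservoir_depth_um <= 0:
        raise ConfigurationError("reservoir_depth_um must be > 0")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file yields the all-defaults configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return _from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML; round-trips through load_config."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON form, for provenance records."""
    import hashlib

    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
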