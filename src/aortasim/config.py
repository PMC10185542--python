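"""Bundled simulator configuration and YAML serialization.

A :class:`SimulatorConfig` groups the five component objects the simulator
needs.  In files, lengths are millimetres and moduli are kilopascals; in
memory everything is SI (plus clinical mmHg pressures).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import yaml

from .cardiac_pump import CardiacProfile
from .vessel_geometry import AortaGeometry, build_standard_aorta
from .wall_material import ChamberPressures, WallMaterial, default_wall_material
from .wave_engine import (
    IVP_OFFSET_DEFAULT,
    PeripheralLoad,
    PressureWaveform,
    SimulationSettings,
    simulate,
)


@dataclass(frozen=True)
class SimulatorConfig:
    geometry: AortaGeometry = field(default_factory=build_standard_aorta)
    material: WallMaterial = field(default_factory=default_wall_material)
    cardiac: CardiacProfile = field(default_factory=CardiacProfile)
    load: PeripheralLoad = field(default_factory=PeripheralLoad)
    pressures: ChamberPressures = field(
        default_factory=lambda: ChamberPressures(IVP_OFFSET_DEFAULT, IVP_OFFSET_DEFAULT)
    )
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    def with_overrides(self, **kwargs) -> "SimulatorConfig":
        """Copy with dotted overrides, e.g. cardiac__hr=90 or load__occlusion_ratio=0.2."""
        cfg = self
        for key, value in kwargs.items():
            section, _, name = key.partition("__")
            if not name:
                cfg = replace(cfg, **{section: value})
            else:
                cfg = replace(cfg, **{section: replace(getattr(cfg, section), **{name: value})})
        return cfg

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "material": self.material.to_dict(),
            "cardiac": dataclasses.asdict(self.cardiac),
            "load": dataclasses.asdict(self.load),
            "pressures": dataclasses.asdict(self.pressures),
            "settings": dataclasses.asdict(self.settings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorConfig":
        base = cls()
        return cls(
            geometry=AortaGeometry.from_dict(d["geometry"]) if "geometry" in d else base.geometry,
            material=WallMaterial.from_dict(d["material"]) if "material" in d else base.material,
            cardiac=CardiacProfile(**d.get("cardiac", {})),
            load=PeripheralLoad(**d.get("load", {})),
            pressures=ChamberPressures(**d.get("pressures", {})),
            settings=SimulationSettings(**d.get("settings", {})),
        )


def standard_config() -> SimulatorConfig:
    """The calibrated standard configuration: HR 75, SV 70, 15% occlusion, TP 0."""
    return SimulatorConfig()


def save_config(config: SimulatorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> SimulatorConfig:
    with open(path) as fh:
        return SimulatorConfig.from_dict(yaml.safe_load(fh))


def simulate_config(
    config: SimulatorConfig, sensor_positions=None, **simulate_kwargs
) -> list[PressureWaveform]:
    """Run the wave engine on a bundled configuration."""
    return simulate(
        config.geometry,
        config.material,
        config.cardiac,
        config.load,
        config.pressures,
        config.settings,
        sensor_positions=sensor_positions,
        **simulate_kwargs,
    )
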