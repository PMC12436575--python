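"""Run configuration: serializable bundle of every stage's parameters.

A :class:`RunConfig` captures the full study definition — pore statistics,
geometry, mesh size, swelling and remodeling constants, Johnson-Cook damage
parameters and seeds — and round-trips losslessly through YAML, so a config
file plus a seed reproduces a campaign bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .ingrowth import RemodelingParams
from .mechanics import JCParams
from .porous_geometry import PoreSpec
from .swelling import SwellingParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or non-round-tripping configuration."""


@dataclass
class RunConfig:
    """Complete campaign configuration (defaults = the reference parameter set)."""

    pore_bands_um: tuple = ((300.0, 100.0), (450.0, 100.0), (600.0, 100.0))
    target_porosity: float = 0.60
    anchor_radius: float = 4.0        # mm
    slice_thickness: float = 2.0      # mm
    bone_layer: float = 1.0           # mm
    element_size: float = 0.05        # mm
    dim: int = 2
    seeds: tuple = (0,)
    swelling: SwellingParams = field(default_factory=SwellingParams)
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    jc: JCParams = field(default_factory=JCParams)
    friction_mu: float = 0.4
    ingrowth_iterations: int = 40
    pushout_displacement: float = 0.5  # mm
    # Interface pressure handed to ingrowth/push-out.  The default is the
    # reported average radial interface stress of the reference 3D swelling
    # simulations (22 MPa); None derives it from this package's own 2D
    # swelling solve instead (plane-strain porous sections percolate poorly,
    # so that value is much lower — see docs/methods.md).
    load_pressure: float | None = 22.0
    output_dir: str = "osteogrow_out"
    write_vtk: bool = False

    def pore_spec(self, band: tuple[float, float], seed: int) -> PoreSpec:
        return PoreSpec(
            mean_diameter_um=band[0], half_band_um=band[1],
            target_porosity=self.target_porosity, rng_seed=seed,
        )

    def remodeling_with(self, **over) -> RemodelingParams:
        return dataclasses.replace(self.remodeling, **over)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pore_bands_um"] = [list(b) for b in self.pore_bands_um]
        d["seeds"] = list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            for key, sub in (("swelling", SwellingParams),
                             ("remodeling", RemodelingParams), ("jc", JCParams)):
                if key in d and isinstance(d[key], dict):
                    d[key] = sub(**d[key])
            if "pore_bands_um" in d:
                d["pore_bands_um"] = tuple(tuple(b) for b in d["pore_bands_um"])
            if "seeds" in d:
                d["seeds"] = tuple(d["seeds"])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return RunConfig.from_dict(data)
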