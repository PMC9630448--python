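"""Run configuration with mandatory unit suffixes.

Physical quantities in config files are strings like ``"25 um"`` or
``"24 keV"`` so that a bare number can never silently be the wrong unit;
unknown keys are rejected.  Parsed values are SI (metres) and keV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .geometry import ImagingGeometry, KernelChoice, MaterialOptics, MATERIALS

__all__ = ["RunConfig", "GeometryConfig", "MaterialConfig", "parse_quantity", "load_config"]

_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_INV_LENGTH = {f"/{u}": 1.0 / s for u, s in _LENGTH.items()} | {
    f"1/{u}": 1.0 / s for u, s in _LENGTH.items()
}
_OTHER = {"keV": 1.0, "px": 1.0, "": 1.0}
_QTY = re.compile(r"^\s*([-+0-9.eE]+)\s*(\S*)\s*$")


def parse_quantity(value: str | float, kind: str) -> float:
    """Parse '25 um' -> 25e-6 (kind='length'), '57.2 /m' -> 57.2, etc.

    kinds: length (-> m), inverse_length (-> 1/m), energy (-> keV),
    pixels (-> px), dimensionless.
    """
    if isinstance(value, (int, float)):
        if kind in ("dimensionless", "pixels"):
            return float(value)
        raise ValueError(f"quantity of kind {kind!r} needs an explicit unit: {value!r}")
    m = _QTY.match(value)
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2)
    tables = {
        "length": _LENGTH,
        "inverse_length": _INV_LENGTH,
        "energy": {"keV": 1.0},
        "pixels": {"px": 1.0, "": 1.0},
        "dimensionless": {"": 1.0},
    }
    table = tables[kind]
    if unit not in table:
        raise ValueError(f"unit {unit!r} invalid for {kind} quantity {value!r}")
    return num * table[unit]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Strict):
    pixel_size: str
    distance: str = "0 m"
    psf_fwhm: str = "0 px"
    shape: tuple[int, int] = (2048, 2048)

    def build(self) -> ImagingGeometry:
        return ImagingGeometry(
            pixel_size=parse_quantity(self.pixel_size, "length"),
            distance=parse_quantity(self.distance, "length"),
            psf_fwhm_px=parse_quantity(self.psf_fwhm, "pixels"),
            shape=tuple(self.shape),
        )


class MaterialConfig(_Strict):
    delta: float
    mu: str
    energy: str = "24 keV"
    density: float = 0.0

    def build(self, name: str = "") -> MaterialOptics:
        return MaterialOptics.from_delta_mu(
            delta=self.delta,
            mu=parse_quantity(self.mu, "inverse_length"),
            energy_keV=parse_quantity(self.energy, "energy"),
            density=self.density,
            name=name,
        )


class SimulationConfig(_Strict):
    radius: str = "900.5 px"
    thickness: str = "6 mm"
    upsample: int = 5
    pre_blur: str = "1.0 px"


class MetrologyConfig(_Strict):
    centre: tuple[float, float] | None = None
    r_min: str = "0 px"
    r_max: str = "0 px"
    arc: tuple[float, float] = (0.0, 360.0)
    bin_width: str = "0.25 px"


class SpectralConfig(_Strict):
    energy_a: str = "30 keV"
    energy_b: str = "40 keV"


class RunConfig(_Strict):
    """Top-level configuration for CLI runs."""

    geometry: GeometryConfig
    materials: dict[str, MaterialConfig] = {}
    kernel: str = "gpm"
    simulation: SimulationConfig = SimulationConfig()
    metrology: MetrologyConfig = MetrologyConfig()
    spectral: SpectralConfig = SpectralConfig()
    seed: int = 0  # only consumed by the optional noise helper

    @field_validator("kernel")
    @classmethod
    def _kernel_known(cls, v: str) -> str:
        KernelChoice(v.lower())
        return v.lower()

    @property
    def kernel_choice(self) -> KernelChoice:
        return KernelChoice(self.kernel)

    def material(self, name: str) -> MaterialOptics:
        if name in self.materials:
            return self.materials[name].build(name)
        if name in MATERIALS:
            return MATERIALS[name]
        raise KeyError(f"unknown material {name!r}")


def load_config(path: str | Path) -> RunConfig:
    data: Any = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig(**data)
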