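"""Leadless-pacemaker device catalogue and volume-preserving design sweeps.

The marketed capsules are modeled as right circular cylinders. Manufacturers
publish lengths; the default diameters here are the manufacturer-nominal
values and are configurable — every result should record the configured
values. Design sweeps vary length while holding the capsule volume fixed
(battery capacity scales with volume), so the diameter follows
``d = 2 sqrt(V / (pi L))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class DeviceSpec:
    """A cylindrical device: length and diameter in mm, volume in mm^3."""

    name: str
    length: float
    diameter: float
    volume: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("device length and diameter must be positive")
        v = math.pi * (self.diameter / 2.0) ** 2 * self.length
        if self.volume == 0.0:
            object.__setattr__(self, "volume", v)
        elif abs(self.volume - v) > 1e-6 * max(v, 1.0):
            raise ValueError(
                f"{self.name}: volume {self.volume} inconsistent with "
                f"pi*(d/2)^2*L = {v}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


#: default catalogue diameters (mm); lengths are the published capsule lengths
_CATALOGUE = (
    ("micra_tps", 25.9, 6.7),
    ("aveir_ar", 32.2, 6.5),
    ("aveir_vr", 38.0, 6.5),
)

#: default sweep lengths, mm
SWEEP_LENGTHS = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)


def catalogue(diameters: dict[str, float] | None = None) -> list[DeviceSpec]:
    """The three contemporary devices (Micra TPS, Aveir AR, Aveir VR).

    ``diameters`` overrides the default nominal diameters by device name.
    """
    diameters = diameters or {}
    return [
        DeviceSpec(name, length, diameters.get(name, diam))
        for name, length, diam in _CATALOGUE
    ]


def volume_preserving_diameter(volume: float, length: float) -> float:
    """Diameter (mm) of a cylinder of given volume (mm^3) and length (mm)."""
    if volume <= 0 or length <= 0:
        raise ValueError("volume and length must be positive")
    return 2.0 * math.sqrt(volume / (math.pi * length))


@dataclass(frozen=True)
class DesignSweep:
    base_device: DeviceSpec
    lengths: tuple[float, ...]
    derived: tuple[DeviceSpec, ...]

    def __post_init__(self) -> None:
        for d in self.derived:
            if abs(d.volume - self.base_device.volume) > 1e-6 * self.base_device.volume:
                raise ValueError("sweep does not preserve device volume")


def build_sweep(base: DeviceSpec,
                lengths: tuple[float, ...] = SWEEP_LENGTHS) -> DesignSweep:
    """Volume-preserving length sweep around ``base``."""
    if any(l <= 0 for l in lengths):
        raise ValueError("sweep lengths must be positive")
    derived = tuple(
        DeviceSpec(
            f"{base.name}_L{l:g}", l, volume_preserving_diameter(base.volume, l)
        )
        for l in lengths
    )
    return DesignSweep(base, tuple(lengths), derived)
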