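"""Ambient conditions and constant air properties.

Properties are evaluated once at 25 °C film conditions and held constant:
over the ≤ 9 K span between ambient air and the mucosal wall their variation
is below 3 %, far under the other modeling idealizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError

__all__ = ["AirProperties", "AmbientConditions", "AIR_25C"]


@dataclass(frozen=True)
class AirProperties:
    """Thermophysical properties of the moist-air mixture (SI)."""

    density: float = 1.184  # kg/m³
    dynamic_viscosity: float = 1.849e-5  # Pa·s
    specific_heat: float = 1006.0  # J/(kg·K)
    prandtl: float = 0.707
    schmidt: float = 0.60
    vapor_diffusivity: float = 2.6e-5  # m²/s
    latent_heat: float = 2.43e6  # J/kg, water at ~34 °C

    @property
    def thermal_conductivity(self) -> float:
        """k = μ·c_p / Pr (W/(m·K))."""
        return self.dynamic_viscosity * self.specific_heat / self.prandtl

    def validate(self) -> None:
        for name in (
            "density",
            "dynamic_viscosity",
            "specific_heat",
            "prandtl",
            "schmidt",
            "vapor_diffusivity",
            "latent_heat",
        ):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"air property {name} must be positive")


@dataclass(frozen=True)
class AmbientConditions:
    """Inhaled-air boundary state and the fixed mucosal wall temperature.

    Defaults are the conventional room condition for nasal air-conditioning
    studies (25 °C, 35 % RH) with a uniform 34 °C mucosal wall — below core
    temperature because the nasal lining itself is cooled by inspired air.
    """

    temperature: float = 25.0  # °C
    relative_humidity: float = 0.35  # fraction
    pressure: float = 101325.0  # Pa, absolute
    wall_temperature: float = 34.0  # °C
    air: AirProperties = field(default_factory=AirProperties)

    def validate(self) -> None:
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise DomainError("relative_humidity must lie in [0, 1]")
        if self.wall_temperature <= self.temperature:
            raise DomainError("wall_temperature must exceed the ambient temperature")
        if self.pressure <= 0.0:
            raise DomainError("pressure must be positive")
        self.air.validate()


AIR_25C = AirProperties()
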