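"""Allometric respiratory quantities and animal profiles.

Tidal volume scales with body mass as ``VT = a M^b`` (avian fit: a = 20.3
ml/kg^b, b = 1.06; the crocodylian fit differs only in a = 20.7).  Air mass
per breath is tidal volume times air density at body temperature.  Breathing
frequency and the high (regression-based) and low (Reversed-Reynolds)
volumetric flow rates are stored constants on each profile: their source
regressions are external and the low rates depend on the real specimen cross
sections, so neither is recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AnimalProfile", "tidal_volume", "air_mass", "default_profiles",
           "AIR_DENSITY_BODY_G_PER_L"]

#: Dry-air density at the 35 degC reference body temperature, g/L.
AIR_DENSITY_BODY_G_PER_L = 1.146


def tidal_volume(mass_kg: float, coefficient: float = 20.3, exponent: float = 1.06) -> float:
    """Tidal volume in ml from body mass in kg (avian allometry by default)."""
    if mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return coefficient * mass_kg**exponent


def air_mass(tidal_volume_l: float, rho_g_per_l: float = AIR_DENSITY_BODY_G_PER_L) -> float:
    """Mass of one breath in grams, from tidal volume in litres."""
    if tidal_volume_l <= 0:
        raise ValueError("tidal volume must be positive")
    if rho_g_per_l <= 0:
        raise ValueError("density must be positive")
    return tidal_volume_l * rho_g_per_l


@dataclass(frozen=True)
class AnimalProfile:
    """Respiratory profile of one animal.

    ``tidal_volume_ml`` defaults to the allometric estimate from
    ``body_mass_kg``; pass an override to pin a published value.
    """

    name: str
    body_mass_kg: float
    body_temperature_c: float = 35.0
    breathing_frequency_min: float = 1.0   # breaths per minute
    flow_high_l_min: float = 1.0
    flow_low_l_min: float = 1.0
    tidal_volume_ml: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        if not 0.0 < self.body_temperature_c < 50.0:
            raise ValueError("body temperature out of physiological range")
        if self.flow_high_l_min <= 0 or self.flow_low_l_min <= 0:
            raise ValueError("flow rates must be positive")
        if self.tidal_volume_ml == 0.0:
            object.__setattr__(self, "tidal_volume_ml", tidal_volume(self.body_mass_kg))
        if self.tidal_volume_ml <= 0:
            raise ValueError("tidal volume must be positive")

    @property
    def tidal_volume_l(self) -> float:
        return self.tidal_volume_ml / 1e3

    @property
    def air_mass_g(self) -> float:
        return air_mass(self.tidal_volume_l)

    def flow_m3_s(self, condition: str = "low") -> float:
        """Volumetric flow in m^3/s for the 'low' or 'high' condition."""
        if condition == "low":
            return self.flow_low_l_min / 60e3
        if condition == "high":
            return self.flow_high_l_min / 60e3
        raise ValueError("condition must be 'low' or 'high'")


def default_profiles() -> dict[str, AnimalProfile]:
    """The two ankylosaur study profiles (lightest published mass estimates).

    High flow rates come from the avian resting-ventilation regression; low
    flow rates are the published Reversed-Reynolds estimates on the real
    specimen cross sections.
    """
    return {
        "panoplosaurus": AnimalProfile(
            name="panoplosaurus", body_mass_kg=1100.0,
            breathing_frequency_min=1.5, flow_high_l_min=77.0, flow_low_l_min=37.0),
        "euoplocephalus": AnimalProfile(
            name="euoplocephalus", body_mass_kg=2000.0,
            breathing_frequency_min=1.2, flow_high_l_min=110.0, flow_low_l_min=48.0),
    }
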