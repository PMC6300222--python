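"""Moist-air state functions.

Saturation vapor pressure uses the Magnus form
``e_s = 610.94 exp(17.625 T / (T + 243.04))`` Pa (T in degC), accurate to a
few tenths of a percent over -40..50 degC.  Water content is available in
two conventions:

* mixing ratio ``w = 0.622 e / (p - e)`` — grams of water per kilogram of
  dry air;
* mass fraction ``w / (1 + w)`` — grams of water per kilogram of moist air.

Respiratory energy budgets in the comparative literature quote "mass
fraction" but tabulated latent totals sit between the two conventions, so
both are exposed; the budget layer selects one (mass fraction by default).

Latent heat of vaporization interpolates a bundled saturated-steam table
(0-100 degC, 5 degC steps, IAPWS-consistent values in kJ/kg, reported in
cal/g).  Air density is ideal-gas dry air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirState",
    "saturation_vapor_pressure",
    "mixing_ratio",
    "water_mass_fraction",
    "water_content",
    "latent_heat",
    "air_density",
    "STEAM_TABLE_C",
    "STEAM_TABLE_CAL_G",
]

_R_DRY = 287.05        # J/(kg K), specific gas constant of dry air
_CAL = 4.184           # J per thermochemical calorie

#: Saturated steam table: temperature (degC) and latent heat of vaporization
#: (kJ/kg).  Standard saturation values at 5 degC steps.
_STEAM_KJ_KG = np.array([
    (0, 2500.9), (5, 2489.0), (10, 2477.2), (15, 2465.4), (20, 2453.5),
    (25, 2441.7), (30, 2429.8), (35, 2417.9), (40, 2406.0), (45, 2394.0),
    (50, 2382.0), (55, 2369.8), (60, 2357.7), (65, 2345.4), (70, 2333.0),
    (75, 2320.6), (80, 2308.0), (85, 2295.3), (90, 2282.5), (95, 2269.5),
    (100, 2256.4),
])
STEAM_TABLE_C = _STEAM_KJ_KG[:, 0]
STEAM_TABLE_CAL_G = _STEAM_KJ_KG[:, 1] / _CAL


@dataclass(frozen=True)
class AirState:
    """Temperature (degC), relative humidity (fraction) and pressure (Pa)."""

    temperature: float
    relative_humidity: float
    pressure: float = 101325.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")
        if not -50.0 < self.temperature < 60.0:
            raise ValueError("temperature outside supported range (-50, 60) degC")

    @staticmethod
    def saturated(temperature: float, pressure: float = 101325.0) -> "AirState":
        return AirState(temperature, 1.0, pressure)


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapor pressure over liquid water, Pa (Magnus form)."""
    if not -50.0 < t_c < 60.0:
        raise ValueError("temperature outside Magnus validity range")
    return 610.94 * float(np.exp(17.625 * t_c / (t_c + 243.04)))


def mixing_ratio(state: AirState) -> float:
    """Grams of water vapor per kilogram of *dry* air."""
    e = state.relative_humidity * saturation_vapor_pressure(state.temperature)
    if e >= state.pressure:
        raise ValueError("vapor pressure exceeds total pressure")
    return 622.0 * e / (state.pressure - e)  # 0.622 kg/kg -> g/kg


def water_mass_fraction(state: AirState) -> float:
    """Grams of water vapor per kilogram of *moist* air."""
    w = mixing_ratio(state) / 1e3
    return w / (1.0 + w) * 1e3


def water_content(state: AirState, convention: str = "mass_fraction") -> float:
    """Water content in g/kg under the chosen convention."""
    if convention == "mass_fraction":
        return water_mass_fraction(state)
    if convention == "mixing_ratio":
        return mixing_ratio(state)
    raise ValueError("convention must be 'mass_fraction' or 'mixing_ratio'")


def latent_heat(t_c: float) -> float:
    """Latent heat of vaporization, cal/g, from the bundled steam table."""
    if t_c < STEAM_TABLE_C[0] or t_c > STEAM_TABLE_C[-1]:
        raise ValueError(
            f"temperature {t_c} degC outside steam table range "
            f"[{STEAM_TABLE_C[0]}, {STEAM_TABLE_C[-1]}]"
        )
    return float(np.interp(t_c, STEAM_TABLE_C, STEAM_TABLE_CAL_G))


def air_density(t_c: float, pressure: float = 101325.0) -> float:
    """Dry-air density, g/L (numerically equal to kg/m^3), ideal gas."""
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    return pressure / (_R_DRY * (t_c + 273.15))
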