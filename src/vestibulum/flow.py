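"""Flow-regime characterisation and duct resistance.

Diagnostics for whether nasal airflow can be treated as steady and laminar:

* Reynolds number ``Re = 4 Q / (P nu)`` per cross section — below 2000 the
  flow is laminar, 2000-4000 transitional, above 4000 turbulent.
* Womersley number ``Wo = (Dh / 2) sqrt(2 pi f / nu)`` — below 1 breathing
  oscillation is slow enough that the flow field is quasi-steady; above 10
  flow never fully develops within a breath.
* The Reversed-Reynolds estimator: solve the Reynolds relation for flow rate
  at a target Re (default 2000, the laminar/transitional boundary) at every
  cross section of the main flow path and take the minimum.  The result is
  the largest volumetric flow at which no cross section leaves the laminar
  range — an upper bound for resting airflow through the passage.

Hagen-Poiseuille serial resistance and the reciprocal-sum parallel rule are
included for comparing a single winding duct against a turbinate-like bank
of narrow parallel channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CenterlineAirway, hydraulic_diameter

__all__ = [
    "FluidProperties",
    "RegimeReport",
    "reynolds",
    "womersley",
    "classify",
    "reversed_reynolds_flow",
    "regime_report",
    "resistance_serial",
    "resistance_parallel",
]


@dataclass(frozen=True)
class FluidProperties:
    """Air properties; defaults for ~15 degC ambient air.

    kinematic_viscosity follows the 1.412e-5 m^2/s value used for the
    published Reynolds calculations.
    """

    kinematic_viscosity: float = 1.412e-5   # m^2/s
    dynamic_viscosity: float = 1.80e-5      # Pa s
    thermal_conductivity: float = 0.0255    # W/(m K)
    specific_heat: float = 1006.0           # J/(kg K)
    reference_temperature: float = 15.0     # degC

    def __post_init__(self) -> None:
        for name in ("kinematic_viscosity", "dynamic_viscosity",
                     "thermal_conductivity", "specific_heat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def reynolds(Q, P, nu: float = 1.412e-5):
    """Re = 4 Q / (P nu) for volumetric flow Q (m^3/s) and wetted perimeter P (m)."""
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0) or nu <= 0:
        raise ValueError("perimeter and kinematic viscosity must be positive")
    if np.any(Q < 0):
        raise ValueError("flow rate must be non-negative")
    out = 4.0 * Q / (P * nu)
    return float(out) if out.ndim == 0 else out


def womersley(Dh, f: float, nu: float = 1.412e-5):
    """Wo = (Dh / 2) sqrt(2 pi f / nu) for breathing frequency f in Hz."""
    Dh = np.asarray(Dh, dtype=float)
    if np.any(Dh <= 0) or nu <= 0:
        raise ValueError("hydraulic diameter and viscosity must be positive")
    if f < 0:
        raise ValueError("frequency must be non-negative")
    out = Dh / 2.0 * math.sqrt(2.0 * math.pi * f / nu)
    return float(out) if out.ndim == 0 else out


def classify(Re: float, Wo: float) -> tuple[str, str]:
    """Map (Re, Wo) to (regime, steadiness) labels.

    Regime: laminar below 2000, transitional on the closed interval
    [2000, 4000], turbulent above.  Steadiness: quasi-steady below Wo=1,
    unsteady above 10, intermediate between (boundaries inclusive).
    """
    if Re < 0 or Wo < 0:
        raise ValueError("Re and Wo must be non-negative")
    if Re < 2000:
        regime = "laminar"
    elif Re <= 4000:
        regime = "transitional"
    else:
        regime = "turbulent"
    if Wo < 1:
        steadiness = "quasi_steady"
    elif Wo > 10:
        steadiness = "unsteady"
    else:
        steadiness = "intermediate"
    return regime, steadiness


def reversed_reynolds_flow(
    airway: CenterlineAirway,
    Re_target: float = 2000.0,
    nu: float = 1.412e-5,
    include_trachea: bool = False,
) -> float:
    """Maximum flow (m^3/s) keeping every main-path section at Re <= target.

    Per station ``Q_i = Re_target P_i nu / 4``; the minimum over the main
    flow path governs.  The olfactory recess (blind side chamber) is always
    excluded; the artificial tracheal extension is excluded by default.
    """
    if Re_target <= 0:
        raise ValueError("Re_target must be positive")
    mask = airway.main_path_mask(include_trachea=include_trachea)
    if not np.any(mask):
        raise ValueError("airway has no stations on the main flow path")
    q = Re_target * airway.perimeter[mask] * nu / 4.0
    return float(q.min())


def regime_report(
    airway: CenterlineAirway,
    Q: float,
    breathing_frequency_hz: float = 0.0,
    fluid: FluidProperties | None = None,
    include_trachea: bool = True,
) -> "RegimeReport":
    """Per-station Re/Wo table plus summary for a given flow rate."""
    fluid = fluid or FluidProperties()
    nu = fluid.kinematic_viscosity
    mask = airway.main_path_mask(include_trachea=include_trachea)
    s = airway.s[mask]
    P = airway.perimeter[mask]
    dh = hydraulic_diameter(airway.area[mask], airway.perimeter[mask])
    re = reynolds(Q, P, nu)
    wo = womersley(dh, breathing_frequency_hz, nu)
    labels = [classify(r, w) for r, w in zip(np.atleast_1d(re), np.atleast_1d(wo))]
    table = pd.DataFrame({
        "s_m": s,
        "Dh_m": dh,
        "Re": re,
        "Wo": wo,
        "regime": [l[0] for l in labels],
        "steadiness": [l[1] for l in labels],
        "region": airway.region[mask],
    })
    return RegimeReport(
        stations=table,
        max_re=float(np.max(re)),
        max_wo=float(np.max(wo)),
        reversed_reynolds_q=reversed_reynolds_flow(airway, nu=nu),
    )


@dataclass
class RegimeReport:
    stations: pd.DataFrame
    max_re: float
    max_wo: float
    reversed_reynolds_q: float

    @property
    def reversed_reynolds_q_l_min(self) -> float:
        return self.reversed_reynolds_q * 60e3


def resistance_serial(mu: float, l: float, r: float) -> float:
    """Hagen-Poiseuille resistance 8 mu l / (pi r^4) of a circular pipe (Pa s/m^3)."""
    if mu <= 0 or l <= 0 or r <= 0:
        raise ValueError("viscosity, length and radius must be positive")
    return 8.0 * mu * l / (math.pi * r**4)


def resistance_parallel(channel_resistances) -> float:
    """Combined resistance of parallel channels: 1 / sum(1/R_i)."""
    R = np.asarray(list(channel_resistances), dtype=float)
    if R.size == 0:
        raise ValueError("at least one channel required")
    if np.any(R <= 0):
        raise ValueError("resistances must be positive")
    return float(1.0 / np.sum(1.0 / R))
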